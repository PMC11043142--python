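"""Gene-level rare-variant burden against reference populations.

The burden statistic is allele-level collapsing: per-variant alt allele
counts are summed over a gene's rare missense variants and divided by a
single population allele number, giving an aggregated allele frequency.
The cohort's aggregated frequency is contrasted with a population's via
the same 2x2 odds-ratio machinery as the per-variant comparisons.  The
gene's variant count is ranked against a CDS-length-matched control-gene
panel, and p-values across a family of comparisons are BH-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datamodel import CohortTable, ControlGeneEntry, GeneModel, VariantRecord
from .enrichment import TwoByTwo, exact_p, or_ci, sample_or
from .populations import GNOMAD_V21_EXOMES, PopulationLabel


@dataclass(frozen=True)
class GeneBurdenResult:
    gene_symbol: str
    population: str
    cohort_agg_ac: int
    cohort_an: int
    pop_agg_af: float
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float | None = None


@dataclass(frozen=True)
class PercentileResult:
    gene_symbol: str
    population: str
    variant_count: int
    percentile: float


def aggregate_af(
    records: list[VariantRecord],
    population: str,
    panel: dict[str, PopulationLabel] | None = None,
) -> tuple[float, float, float]:
    """Aggregated (alt count, allele number, frequency) over one gene.

    Alt counts are summed across variants; the denominator is the single
    per-population allele number (allele-level collapsing), so the result
    is the expected count of gene alt alleles per sampled chromosome.
    Records must all come from one gene (one contig here).
    """
    panel = panel if panel is not None else GNOMAD_V21_EXOMES
    if len({r.contig for r in records}) > 1:
        raise ValueError("aggregate_af expects records from a single gene")
    if population not in panel:
        raise ValueError(f"unknown population {population!r}")
    an = float(panel[population].allele_number)
    if not records:
        return 0.0, an, 0.0
    agg_ac = 0.0
    site_ans = set()
    for r in records:
        pf = r.per_pop.get(population)
        if pf is not None:
            agg_ac += pf.count
            site_ans.add(pf.an)
    # Single-AN convention: a shared per-site override wins over the panel
    # default; heterogeneous site ANs fall back to their maximum (the
    # best-covered sites define the denominator).
    if site_ans:
        an = float(max(site_ans))
    if agg_ac > an:
        raise ValueError(
            f"aggregated {population} allele count {agg_ac:.1f} exceeds the "
            f"allele number {an:.0f}: allele-level collapsing is only "
            "meaningful for sparse rare-variant sets (sum of AFs < 1)"
        )
    return agg_ac, an, agg_ac / an


def gene_burden_or(
    cohort: CohortTable,
    records: list[VariantRecord] | None = None,
    population: str = "NFE",
    panel: dict[str, PopulationLabel] | None = None,
    gene_symbol: str = "",
) -> GeneBurdenResult:
    """Cohort-vs-population aggregated odds ratio for one gene.

    ``records`` default to the cohort's own variants (whose per-population
    frequencies then provide the reference side).  With a single variant
    this reduces exactly to that variant's cross-product OR.
    """
    records = list(cohort.variants) if records is None else records
    agg_ac, agg_an, agg_af = aggregate_af(records, population, panel)
    cohort_ac = cohort.aggregated_ac
    table = TwoByTwo(
        float(cohort_ac), float(cohort.cohort_an - cohort_ac),
        agg_ac, agg_an - agg_ac,
    )
    low, high = or_ci(table)
    return GeneBurdenResult(
        gene_symbol=gene_symbol,
        population=population,
        cohort_agg_ac=cohort_ac,
        cohort_an=cohort.cohort_an,
        pop_agg_af=agg_af,
        or_point=sample_or(table),
        ci_low=low,
        ci_high=high,
        p_value=exact_p(table),
    )


def select_controls(
    candidates: list[ControlGeneEntry], focal: GeneModel, tolerance: int = 439
) -> list[ControlGeneEntry]:
    """Controls within ``tolerance`` bp of the focal CDS length.

    Sorted by |length difference|, ties broken by gene symbol.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    kept = [
        c for c in candidates if abs(c.cds_length - focal.cds_length) <= tolerance
    ]
    return sorted(kept, key=lambda c: (abs(c.cds_length - focal.cds_length), c.gene_symbol))


def fdr_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def attach_qvalues(results: list[GeneBurdenResult]) -> list[GeneBurdenResult]:
    """BH-adjust p-values across a family of burden results."""
    from dataclasses import replace

    qs = fdr_adjust([r.p_value for r in results])
    return [replace(r, q_value=q) for r, q in zip(results, qs)]


def percentile_rank(
    panel: list[ControlGeneEntry],
    focal_count: int,
    population: str,
    gene_symbol: str = "",
) -> PercentileResult:
    """Midrank percentile of the focal gene's variant count in the panel.

    percentile = 100 * (#controls strictly below + 0.5 * #ties) / (n + 1),
    where n is the panel size; the +1 places the focal gene inside its own
    ranking so the result stays inside (0, 100).
    """
    if not panel:
        raise ValueError("control panel must be non-empty")
    counts = np.array([c.count(population) for c in panel])
    below = int(np.sum(counts < focal_count))
    ties = int(np.sum(counts == focal_count))
    percentile = 100.0 * (below + 0.5 * ties) / (len(panel) + 1)
    return PercentileResult(
        gene_symbol=gene_symbol,
        population=population,
        variant_count=focal_count,
        percentile=percentile,
    )
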