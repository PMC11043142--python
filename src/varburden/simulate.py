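"""Synthetic gnomAD-style data with known ground truth.

The generator emulates the statistical skeleton of a multi-population
exome frequency database and a small sequenced cohort:

* per-variant true allele frequencies drawn log-uniformly in the rare
  range, shared across populations under the null;
* planted cross-population enrichments on the odds scale, so a target
  odds ratio is the estimand the downstream comparison should recover;
* variant positions from a thinned uniform point process along the CDS —
  segments with an intensity multiplier < 1 are planted low-density
  (constrained-like) regions;
* cohort allele counts drawn binomially out of 2 x n_probands alleles;
* a control-gene panel with CDS lengths scattered around the focal gene
  and Poisson variant counts proportional to length;
* genotypes built from four-haplotype frequency tables that achieve
  requested pairwise r² values exactly in expectation.

Everything is driven by one seed; per-stage generators are derived with
fixed spawn keys, so stages are reproducible independently of each other.
Defaults mirror the study conditions: the gnomAD v2.1 exome population
sizes, a 100-proband cohort (200 alleles), an 8,778-bp CDS, a 64-gene
control panel within +-439 bp, and an AF < 0.01 rarity regime.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    CohortTable,
    ControlGeneEntry,
    GeneModel,
    PopFrequency,
    VariantRecord,
    single_interval_gene,
)
from .ld import GenotypeMatrix, max_feasible_r2
from .populations import make_panel

#: gnomAD v2.1 exome diploid sizes of the five continental populations.
DEFAULT_POPULATIONS: dict[str, int] = {
    "NFE": 56_885,
    "AFR": 8_128,
    "EAS": 9_197,
    "SAS": 15_308,
    "AMR": 17_296,
}


def default_gene() -> GeneModel:
    """An OTOG-like focal gene: one 8,778-bp CDS block."""
    return single_interval_gene("GENE1", 8_778, contig="chr11", start=17_000_000)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    populations: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS)
    )
    gene: GeneModel = field(default_factory=default_gene)
    n_variants: int = 2_000
    #: log-uniform bounds for the per-variant baseline AF, within (0, 0.01).
    #: The default spans singleton-scale frequencies to 1e-3, a rare-site
    #: spectrum whose sum over a gene's variants stays well below 1 — the
    #: regime in which aggregated (allele-level collapsed) frequencies are
    #: meaningful.
    baseline_af_range: tuple[float, float] = (2e-6, 1e-3)
    af_threshold: float = 0.01
    #: (variant index, (enriched pop, baseline pop), target odds ratio);
    #: indices refer to the position-sorted variants that survive thinning
    planted_enrichments: tuple[tuple[int, tuple[str, str], float], ...] = ()
    #: ((cds start, cds end) 0-based half-open, intensity multiplier in [0, 1))
    ldr_segments: tuple[tuple[tuple[int, int], float], ...] = ()
    cohort_n_probands: int = 100
    cohort_reference: str = "NFE"
    #: odds multiplier applied to the reference AF when drawing cohort counts
    cohort_odds_ratio: float = 1.0
    #: (variant index, planted cohort allele count)
    planted_cohort_ac: tuple[tuple[int, int], ...] = ()
    n_control_genes: int = 64
    control_length_spread: int = 439
    #: per-population rare-missense rate per CDS bp; None derives rates from
    #: the population allele-number shares of the simulated variant count
    control_rates: dict[str, float] | None = None
    #: ((variant index pair), target r2, (minor AF 1, minor AF 2)); the
    #: defaults plant the three linkage magnitudes of interest — moderate,
    #: strong and perfect — on separate variant pairs
    ld_blocks: tuple[tuple[tuple[int, int], float, tuple[float, float]], ...] = (
        ((0, 1), 0.332, (0.05, 0.05)),
        ((2, 3), 0.832, (0.10, 0.10)),
        ((4, 5), 1.0, (0.30, 0.30)),
    )
    ld_n_individuals: int = 2_504
    #: MAF range for LD variants not constrained by a block
    ld_background_maf: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        lo, hi = self.baseline_af_range
        if not 0.0 < lo < hi < 0.01 + 1e-12:
            raise ValueError("baseline_af_range must satisfy 0 < low < high <= 0.01")
        for idx, (p1, p2), target in self.planted_enrichments:
            if target <= 0:
                raise ValueError(f"target odds ratio must be > 0, got {target}")
            for code in (p1, p2):
                if code not in self.populations:
                    raise ValueError(f"unknown population {code!r} in enrichment")
        for (start, end), mult in self.ldr_segments:
            if not 0 <= start < end <= self.gene.cds_length:
                raise ValueError(f"LDR segment [{start}, {end}) outside CDS")
            if not 0.0 <= mult < 1.0:
                raise ValueError(
                    f"LDR multiplier must lie in [0, 1) to be detectable, got {mult}"
                )
        for _, r2, _ in self.ld_blocks:
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"target r2 must lie in [0, 1], got {r2}")
        if self.cohort_odds_ratio <= 0:
            raise ValueError("cohort_odds_ratio must be > 0")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside generated data."""

    true_af: dict[str, dict[str, float]] = field(default_factory=dict)
    ldr_segments: list[tuple[int, int, float]] = field(default_factory=list)
    true_r2: dict[str, float] = field(default_factory=dict)
    control_expected: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_or: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n"
        )


def _enriched_af(baseline: float, odds_ratio: float) -> float:
    odds = odds_ratio * baseline / (1.0 - baseline)
    return odds / (1.0 + odds)


def _cds_to_genomic(gene: GeneModel, cds_pos: int) -> tuple[str, int]:
    """Map a 1-based CDS position through the gene's exon intervals."""
    remaining = cds_pos
    for contig, start, end in gene.cds_intervals:
        span = end - start
        if remaining <= span:
            return contig, start + remaining  # 1-based genomic position
        remaining -= span
    raise ValueError(f"cds_pos {cds_pos} beyond CDS length {gene.cds_length}")


def simulate_frequency_table(
    config: SimulationConfig,
) -> tuple[list[VariantRecord], SyntheticTruth]:
    """Draw a multi-population variant frequency table plus its truth.

    Positions are a thinned uniform process: ``n_variants`` distinct CDS
    positions are drawn, then each inside a planted low-density segment is
    kept only with that segment's multiplier as probability.  True AFs are
    shared across populations except where an enrichment is planted by
    solving ``odds(p_target) = OR * odds(p_baseline)``; allele counts are
    binomial at each population's allele number, and the GLOBAL column is
    the sum over populations.
    """
    rng = config.rng(0)
    gene = config.gene
    length = gene.cds_length
    panel = make_panel(config.populations)

    positions = 1 + rng.choice(length, size=min(config.n_variants, length), replace=False)
    keep = np.ones(len(positions), dtype=bool)
    for (start, end), mult in config.ldr_segments:
        inside = (positions > start) & (positions <= end)
        keep &= ~inside | (rng.random(len(positions)) < mult)
    positions = np.sort(positions[keep])

    lo, hi = config.baseline_af_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(positions)))

    enrichments: dict[int, list[tuple[str, str, float]]] = {}
    for idx, (pop_hi, pop_base), target in config.planted_enrichments:
        if not 0 <= idx < len(positions):
            raise ValueError(
                f"enrichment index {idx} out of range for {len(positions)} "
                "surviving variants"
            )
        enrichments.setdefault(idx, []).append((pop_hi, pop_base, target))

    records: list[VariantRecord] = []
    truth = SyntheticTruth(
        ldr_segments=[(s, e, m) for (s, e), m in config.ldr_segments]
    )
    codes = list(config.populations)
    for i, (cds_pos, base) in enumerate(zip(positions, baselines)):
        true_af = {code: float(base) for code in codes}
        for pop_hi, pop_base, target in enrichments.get(i, []):
            enriched = _enriched_af(true_af[pop_base], target)
            if enriched >= config.af_threshold:
                raise ValueError(
                    f"variant {i}: planted AF {enriched:.4g} crosses the "
                    f"rarity threshold {config.af_threshold}; use a smaller "
                    "baseline or target odds ratio"
                )
            true_af[pop_hi] = enriched
        per_pop: dict[str, PopFrequency] = {}
        global_ac = 0
        global_an = 0
        for code in codes:
            an = panel[code].allele_number
            ac = int(rng.binomial(an, true_af[code]))
            per_pop[code] = PopFrequency(an=an, ac=ac)
            global_ac += ac
            global_an += an
        per_pop["GLOBAL"] = PopFrequency(an=global_an, ac=global_ac)
        contig, gpos = _cds_to_genomic(gene, int(cds_pos))
        record = VariantRecord(
            contig=contig,
            pos=gpos,
            ref="A",
            alt="G",
            consequence="missense",
            cds_pos=int(cds_pos),
            per_pop=per_pop,
        )
        records.append(record)
        truth.true_af[record.key] = true_af
        for pop_hi, pop_base, target in enrichments.get(i, []):
            truth.planted_or[f"{record.key}:{pop_hi}:{pop_base}"] = target
    return records, truth


def simulate_cohort(
    config: SimulationConfig, records: list[VariantRecord]
) -> CohortTable:
    """Attach cohort allele counts out of ``2 * n_probands`` alleles.

    Counts are planted where specified, otherwise binomial at the
    reference-population AF with the configured odds multiplier applied.
    """
    if config.cohort_n_probands <= 0:
        raise ValueError("cohort_n_probands must be positive")
    rng = config.rng(1)
    an = 2 * config.cohort_n_probands
    planted = dict()
    for idx, ac in config.planted_cohort_ac:
        if not 0 <= idx < len(records):
            raise ValueError(f"planted cohort index {idx} out of range")
        if ac > an:
            raise ValueError(
                f"planted cohort AC {ac} exceeds 2 x n_probands = {an}"
            )
        planted[idx] = ac
    out = []
    for i, record in enumerate(records):
        if i in planted:
            ac = planted[i]
        else:
            p_ref = record.af(config.cohort_reference)
            p = (
                _enriched_af(p_ref, config.cohort_odds_ratio)
                if 0.0 < p_ref < 1.0
                else p_ref
            )
            ac = int(rng.binomial(an, p))
        out.append(record.with_cohort(ac, an))
    return CohortTable(
        variants=tuple(out),
        n_probands=config.cohort_n_probands,
        reference_population=config.cohort_reference,
        af_threshold=config.af_threshold,
    )


def cohort_truth_or(config: SimulationConfig, truth: SyntheticTruth) -> float:
    """Aggregated cohort-vs-reference odds ratio implied by the true AFs.

    Cohort counts are planted per variant on the odds scale, so the
    gene-level estimand is the odds ratio of the *summed* true frequencies
    (slightly above ``cohort_odds_ratio`` once the aggregated cohort
    frequency leaves the rare regime, because odds are convex in AF).
    """
    ref = config.cohort_reference
    sum_ref = sum(af[ref] for af in truth.true_af.values())
    sum_coh = sum(
        _enriched_af(af[ref], config.cohort_odds_ratio)
        for af in truth.true_af.values()
    )
    odds = lambda p: p / (1.0 - p)  # noqa: E731
    return odds(sum_coh) / odds(sum_ref)


def _control_rates(config: SimulationConfig) -> dict[str, float]:
    """Per-population per-bp rates of *carried* rare-missense sites.

    Matched to a null focal gene: the expected number of sites with
    AC > 0 in a population is ``n_variants * E[1 - (1-p)^AN]`` under the
    baseline AF law, so control counts and the focal gene's carried-site
    counts live on one scale.
    """
    if config.control_rates is not None:
        return dict(config.control_rates)
    lo, hi = config.baseline_af_range
    p = np.exp(np.linspace(math.log(lo), math.log(hi), 257))
    out = {}
    for code, n in config.populations.items():
        carried = float(np.mean(1.0 - np.power(1.0 - p, 2 * n)))
        out[code] = config.n_variants * carried / config.gene.cds_length
    return out


def simulate_control_panel(config: SimulationConfig) -> list[ControlGeneEntry]:
    """CDS-length-matched control genes with Poisson variant counts."""
    if config.n_control_genes < 1:
        raise ValueError("n_control_genes must be >= 1")
    rng = config.rng(2)
    rates = _control_rates(config)
    length0 = config.gene.cds_length
    spread = config.control_length_spread
    entries = []
    for k in range(config.n_control_genes):
        cds_length = int(rng.integers(length0 - spread, length0 + spread + 1))
        counts = {
            code: int(rng.poisson(rate * cds_length))
            for code, rate in rates.items()
        }
        entries.append(
            ControlGeneEntry(
                gene_symbol=f"CTRL{k + 1:03d}",
                cds_length=cds_length,
                rare_missense_count=counts,
            )
        )
    return entries


def control_expected_counts(config: SimulationConfig) -> dict[str, float]:
    """Expected per-population count for a gene of the focal CDS length."""
    return {
        code: rate * config.gene.cds_length
        for code, rate in _control_rates(config).items()
    }


def haplotype_frequencies(r2: float, p_a: float, p_b: float) -> np.ndarray:
    """Four-haplotype frequencies (AB, Ab, aB, ab) achieving r² with D > 0."""
    for p in (p_a, p_b):
        if not 0.0 < p < 1.0:
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
    feasible = max_feasible_r2(p_a, p_b)
    if r2 > feasible + 1e-12:
        raise ValueError(
            f"target r2={r2} infeasible for AFs {p_a}/{p_b}; "
            f"feasible maximum is {feasible:.4g}"
        )
    d = math.sqrt(r2 * p_a * (1 - p_a) * p_b * (1 - p_b))
    freqs = np.array(
        [
            p_a * p_b + d,
            p_a * (1 - p_b) - d,
            (1 - p_a) * p_b - d,
            (1 - p_a) * (1 - p_b) + d,
        ]
    )
    freqs = np.clip(freqs, 0.0, 1.0)
    return freqs / freqs.sum()


def simulate_genotypes(
    config: SimulationConfig, n_variants: int | None = None
) -> GenotypeMatrix:
    """Diploid genotypes with planted pairwise r².

    Each LD block builds the four-haplotype table achieving its target r²
    and samples two haplotypes per individual independently (no
    recombination, no structure); variants outside any block segregate
    independently at background MAFs.
    """
    rng = config.rng(3)
    blocks = config.ld_blocks
    used = [i for (pair, _, _) in blocks for i in pair]
    if len(used) != len(set(used)):
        raise ValueError("a variant may appear in at most one LD block")
    n_var = n_variants if n_variants is not None else (max(used, default=-1) + 1)
    if n_var < 1:
        raise ValueError("need at least one variant (none referenced by ld_blocks)")
    if used and max(used) >= n_var:
        raise ValueError("ld_blocks reference variant indices out of range")
    n = config.ld_n_individuals
    haps = np.zeros((2 * n, n_var), dtype=np.int8)
    in_block = set(used)
    for (i, j), r2, (p_a, p_b) in blocks:
        freqs = haplotype_frequencies(r2, p_a, p_b)
        draws = rng.choice(4, size=2 * n, p=freqs)
        haps[:, i] = (draws <= 1).astype(np.int8)  # AB or Ab -> allele A
        haps[:, j] = ((draws == 0) | (draws == 2)).astype(np.int8)
    lo, hi = config.ld_background_maf
    for k in range(n_var):
        if k not in in_block:
            maf = rng.uniform(lo, hi)
            haps[:, k] = (rng.random(2 * n) < maf).astype(np.int8)
    dosages = haps[0::2] + haps[1::2]
    return GenotypeMatrix(
        individuals=tuple(f"I{i + 1:05d}" for i in range(n)),
        variant_ids=tuple(f"v{k}" for k in range(n_var)),
        dosages=dosages.astype(np.int64),
        phased_haplotypes=haps.astype(np.int64),
    )


def genotype_truth(config: SimulationConfig) -> dict[str, float]:
    """Planted r² per variant-id pair, keyed ``"vI-vJ"``."""
    return {f"v{i}-v{j}": r2 for (i, j), r2, _ in config.ld_blocks}
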