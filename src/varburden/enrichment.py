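"""Per-variant cross-population allele-frequency comparison.

For each variant and ordered population pair ``(pop1, pop2)`` a 2x2
allele-count table is reconstructed,

====================  ==============  ==============
                      alt alleles     ref alleles
pop1                  a               b
pop2                  c               d
====================  ==============  ==============

and summarized by the sample (cross-product) odds ratio ``(a*d)/(b*c)``
with a 95% confidence interval and a two-sided Fisher exact p-value.  A
variant is *enriched* in pop1 when OR >= 1 and p < alpha, *depleted* when
OR < 1 and p < alpha.

Because public frequency databases print rounded AFs, cells reconstructed
from AF alone are kept as real numbers (``AF * AN``) by default: rounding
an implied count of 2.4 down to 2 distorts the odds ratio of a rare
variant by double-digit percentages.  Rounding to the nearest integer is
applied internally only where a discrete test demands counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import VariantRecord
from .populations import COHORT_CODE, PopulationLabel

HALDANE = "haldane"
NONE_POLICY = "none"


@dataclass(frozen=True)
class TwoByTwo:
    """Allele-count contingency table; cells may be real-valued."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} negative: {getattr(self, name)}")
        if self.an1 <= 0 or self.an2 <= 0:
            raise ValueError("both margins (allele numbers) must be positive")

    @property
    def an1(self) -> float:
        return self.a + self.b

    @property
    def an2(self) -> float:
        return self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0.0 in (self.a, self.b, self.c, self.d)

    def rounded(self) -> "TwoByTwo":
        """Nearest-integer cells, margins preserved via the alt cell."""
        a, c = round(self.a), round(self.c)
        return TwoByTwo(a, round(self.an1) - a, c, round(self.an2) - c)

    def haldane(self) -> "TwoByTwo":
        """Add 0.5 to every cell (only used when a zero cell is present)."""
        return TwoByTwo(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class EnrichmentResult:
    variant: str
    pop1: str
    pop2: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    method_ci: str
    enriched: bool = False
    depleted: bool = False


def _side(
    variant: VariantRecord, code: str, panel: dict[str, PopulationLabel] | None
) -> tuple[float, float]:
    """(alt count, allele number) for one comparison side, real-valued."""
    if code == COHORT_CODE:
        if variant.cohort_ac is None or variant.cohort_an is None:
            raise ValueError(f"{variant.key}: no cohort counts for {COHORT_CODE!r}")
        return float(variant.cohort_ac), float(variant.cohort_an)
    pf = variant.per_pop.get(code)
    if pf is not None:
        return pf.count, float(pf.an)
    # Absent population: frequency zero at the panel allele number.
    if panel is None or code not in panel:
        raise ValueError(
            f"{variant.key}: population {code!r} absent from record and panel"
        )
    return 0.0, float(panel[code].allele_number)


def build_table(
    variant: VariantRecord,
    pop1: str,
    pop2: str,
    panel: dict[str, PopulationLabel] | None = None,
    rounding: str = "none",
) -> TwoByTwo:
    """Reconstruct the 2x2 allele-count table for one population pair.

    ``rounding="nearest"`` rounds AF-implied counts to integers;
    ``"none"`` (default) keeps them real-valued, which is what reproduces
    odds ratios computed from published rounded AFs.
    """
    ac1, an1 = _side(variant, pop1, panel)
    ac2, an2 = _side(variant, pop2, panel)
    table = TwoByTwo(ac1, an1 - ac1, ac2, an2 - ac2)
    if rounding == "nearest":
        return table.rounded()
    if rounding != "none":
        raise ValueError(f"unknown rounding {rounding!r}")
    return table


def sample_or(table: TwoByTwo, zero_policy: str = NONE_POLICY) -> float:
    """Sample cross-product odds ratio ``(a*d)/(b*c)``.

    With the default ``"none"`` policy a zero alt count in pop2 yields
    ``inf`` and a zero alt count in pop1 yields ``0.0``; the ``"haldane"``
    policy adds 0.5 to every cell first whenever any cell is zero.
    """
    if zero_policy == HALDANE and table.has_zero_cell:
        table = table.haldane()
    elif zero_policy not in (NONE_POLICY, HALDANE):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if table.b * table.c == 0.0:
        if table.a * table.d == 0.0:
            return math.nan  # doubly degenerate: no information
        return math.inf
    return (table.a * table.d) / (table.b * table.c)


def or_ci(table: TwoByTwo, level: float = 0.95, method: str = "woolf") -> tuple[float, float]:
    """Confidence interval for the odds ratio.

    ``woolf``: exp(log OR +- z * sqrt(1/a + 1/b + 1/c + 1/d)), computed on
    the Haldane-corrected table when any cell is zero.  ``exact``: the
    conditional (noncentral hypergeometric) interval inverting Fisher's
    exact test, on nearest-integer counts.

    A degenerate table (no alt alleles anywhere, or no ref alleles)
    carries no information about the OR; ``(nan, nan)`` is returned.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    if table.a + table.c == 0 or table.b + table.d == 0:
        return (math.nan, math.nan)
    if method == "woolf":
        t = table.haldane() if table.has_zero_cell else table
        z = stats.norm.ppf(0.5 + level / 2)
        log_or = math.log((t.a * t.d) / (t.b * t.c))
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        return (math.exp(log_or - z * se), math.exp(log_or + z * se))
    if method == "exact":
        t = table.rounded()
        res = stats.contingency.odds_ratio(
            [[int(t.a), int(t.b)], [int(t.c), int(t.d)]], kind="conditional"
        )
        ci = res.confidence_interval(confidence_level=level)
        return (float(ci.low), float(ci.high))
    raise ValueError(f"unknown CI method {method!r}")


def exact_p(table: TwoByTwo) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood rule).

    Conditional on both margins, the alt count in pop1 follows a
    hypergeometric law; the p-value sums the probabilities of all tables
    no more probable than the one observed.  Real-valued cells are rounded
    to the nearest integers first.
    """
    t = table.rounded()
    a, b, c, d = (int(t.a), int(t.b), int(t.c), int(t.d))
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    support_lo = max(0, col1 - (c + d))
    support_hi = min(row1, col1)
    ks = np.arange(support_lo, support_hi + 1)
    pmf = stats.hypergeom.pmf(ks, n_total, row1, col1)
    observed = stats.hypergeom.pmf(a, n_total, row1, col1)
    # Tolerance handles ties degraded by floating point.
    p = float(pmf[pmf <= observed * (1 + 1e-9)].sum())
    return min(1.0, p)


def classify_enrichment(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Set enriched/depleted flags: OR >= 1 (resp. < 1) and p < alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    out = []
    for r in results:
        significant = r.p_value < alpha and not math.isnan(r.or_point)
        out.append(
            replace(
                r,
                enriched=significant and r.or_point >= 1.0,
                depleted=significant and r.or_point < 1.0,
            )
        )
    return out


def enrich_variants(
    records: list[VariantRecord],
    pairs: list[tuple[str, str]],
    panel: dict[str, PopulationLabel] | None = None,
    alpha: float = 0.05,
    ci_method: str = "woolf",
    zero_policy: str = NONE_POLICY,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Run all (variant, population pair) comparisons into one DataFrame.

    When ``bh_adjust`` is set a ``q_value`` column with Benjamini-Hochberg
    adjusted p-values across all comparisons is appended; the published
    analysis reports raw p-values.
    """
    results = []
    for record in records:
        for pop1, pop2 in pairs:
            table = build_table(record, pop1, pop2, panel=panel)
            low, high = or_ci(table, 0.95, ci_method)
            results.append(
                EnrichmentResult(
                    variant=record.key,
                    pop1=pop1,
                    pop2=pop2,
                    or_point=sample_or(table, zero_policy),
                    ci_low=low,
                    ci_high=high,
                    p_value=exact_p(table),
                    method_ci=ci_method,
                )
            )
    results = classify_enrichment(results, alpha)
    df = pd.DataFrame([r.__dict__ for r in results])
    if bh_adjust and len(df):
        from statsmodels.stats.multitest import multipletests

        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
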