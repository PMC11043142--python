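"""Sliding-window missense variant density along a coding sequence.

At every CDS position ``i`` (1-based, step 1 by default) the density is
the number of distinct variant sites observed in the window
``[i - h, i + h]`` (``h`` = 100 bp by default, so a 201-bp window)
divided by the window length.  Windows are clipped at the CDS termini and
divided by the clipped length, avoiding artifactual low density at the
ends.  A position is a low-density region (LDR, "constrained") when its
density falls strictly below a population-scaled expected density, and a
high-density region (HDR) otherwise; maximal runs of equal labels
partition the CDS into regions.

A "variant" here is a distinct site carried by at least one allele in the
population considered, counted once regardless of its frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import GeneModel, VariantRecord
from .populations import COHORT_CODE, GNOMAD_V21_EXOMES, PopulationLabel

LDR = "LDR"
HDR = "HDR"


@dataclass
class DensityProfile:
    population: str
    cds_length: int
    window_halfwidth: int
    step: int
    density: np.ndarray  # index i-1 <-> CDS position i; variants/bp
    threshold: float | None = None

    @property
    def labels(self) -> np.ndarray:
        """Per-position LDR/HDR labels (requires a threshold)."""
        if self.threshold is None:
            raise ValueError("no threshold set on this profile")
        return np.where(self.density < self.threshold, LDR, HDR)

    def with_threshold(self, threshold: float) -> "DensityProfile":
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        return DensityProfile(
            self.population, self.cds_length, self.window_halfwidth,
            self.step, self.density, threshold,
        )


@dataclass(frozen=True)
class RegionSet:
    """Maximal-run LDR/HDR segmentation, half-open on CDS coordinates."""

    population: str
    cds_length: int
    regions: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        cursor = 0
        prev_label = None
        for start, end, label in self.regions:
            if start != cursor or end <= start:
                raise ValueError("regions must partition [0, cds_length)")
            if label == prev_label:
                raise ValueError("adjacent regions must alternate labels")
            cursor, prev_label = end, label
        if cursor != self.cds_length:
            raise ValueError("regions must cover the full CDS")

    def label_array(self) -> np.ndarray:
        out = np.empty(self.cds_length, dtype=object)
        for start, end, label in self.regions:
            out[start:end] = label
        return out

    @property
    def ldr_length(self) -> int:
        return sum(end - start for start, end, lab in self.regions if lab == LDR)


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected missense variant counts, gnomAD-constraint style.

    ``overall`` is the expected count for the whole release; per-population
    expectations are direct proportions ``overall * scale[pop]`` with
    scales in (0, 1] and the global scale fixed at 1.
    """

    overall: float
    scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.overall <= 0:
            raise ValueError("overall expected count must be positive")
        for code, s in self.scale.items():
            if not 0.0 < s <= 1.0:
                raise ValueError(f"scale for {code} must lie in (0, 1], got {s}")

    def expected(self, population: str) -> float:
        if population == "GLOBAL":
            return self.overall
        if population not in self.scale:
            raise ValueError(f"no expected-count scale for population {population!r}")
        return self.overall * self.scale[population]


def an_share_scales(
    panel: dict[str, PopulationLabel] | None = None,
) -> dict[str, float]:
    """Per-population scales as allele-number share of the global panel."""
    panel = panel if panel is not None else GNOMAD_V21_EXOMES
    total = panel["GLOBAL"].allele_number
    return {
        code: pop.allele_number / total
        for code, pop in panel.items()
        if code != "GLOBAL"
    }


def observed_share_scales(
    variants: list[VariantRecord], panel: dict[str, PopulationLabel] | None = None
) -> dict[str, float]:
    """Alternative scales: share of observed variant sites per population."""
    panel = panel if panel is not None else GNOMAD_V21_EXOMES
    total = sum(1 for v in variants if any(pf.count > 0 for pf in v.per_pop.values()))
    if total == 0:
        raise ValueError("no observed variant in any population")
    return {
        code: max(1, sum(1 for v in variants if _carried(v, code))) / total
        for code in panel
        if code != "GLOBAL"
    }


def _carried(variant: VariantRecord, population: str) -> bool:
    if population == COHORT_CODE:
        return bool(variant.cohort_ac)
    pf = variant.per_pop.get(population)
    return pf is not None and pf.count > 0


def density_profile(
    variants: list[VariantRecord],
    gene: GeneModel,
    population: str,
    halfwidth: int = 100,
    step: int = 1,
) -> DensityProfile:
    """Sliding-window variant density at every CDS position.

    With ``step > 1`` the density is evaluated at positions 1, 1+step, ...
    and held constant until the next evaluation so the per-position array
    always spans the full CDS.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    length = gene.cds_length
    missing = [v.key for v in variants if _carried(v, population) and v.cds_pos is None]
    if missing:
        raise ValueError(f"variants lack cds_pos: {', '.join(missing)}")
    sites = sorted({v.cds_pos for v in variants if _carried(v, population)})
    for pos in sites:
        if not 1 <= pos <= length:
            raise ValueError(f"cds_pos {pos} outside CDS of length {length}")
    counts = np.zeros(length + 1, dtype=np.int64)
    if sites:
        counts[np.array(sites)] = 1
    csum = np.concatenate([[0], np.cumsum(counts)])  # csum[p] = sites <= p-? see below
    # csum[p+1] - csum[q] = number of sites with q <= pos <= p
    positions = np.arange(1, length + 1)
    lo = np.maximum(positions - halfwidth, 1)
    hi = np.minimum(positions + halfwidth, length)
    window_counts = csum[hi + 1] - csum[lo]
    window_lengths = hi - lo + 1
    dens = window_counts / window_lengths
    if step > 1:
        eval_idx = np.arange(0, length, step)
        hold = np.repeat(dens[eval_idx], step)[:length]
        dens = hold
    return DensityProfile(
        population=population,
        cds_length=length,
        window_halfwidth=halfwidth,
        step=step,
        density=dens,
    )


def population_threshold(
    expected: ExpectedCounts, gene: GeneModel, population: str
) -> float:
    """Expected density threshold: expected count in the population / CDS length."""
    return expected.expected(population) / gene.cds_length


def call_regions(profile: DensityProfile) -> RegionSet:
    """Merge per-position labels into the maximal-run LDR/HDR partition."""
    labels = profile.labels
    boundaries = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [profile.cds_length]])
    return RegionSet(
        population=profile.population,
        cds_length=profile.cds_length,
        regions=tuple(
            (int(s), int(e), str(labels[s])) for s, e in zip(starts, ends)
        ),
    )


def annotate_variant_region(regions: RegionSet, variant: VariantRecord) -> str:
    """LDR/HDR label of the region containing the variant's CDS position."""
    if variant.cds_pos is None or not 1 <= variant.cds_pos <= regions.cds_length:
        raise ValueError(
            f"{variant.key}: cds_pos {variant.cds_pos} outside CDS "
            f"[1, {regions.cds_length}]"
        )
    idx = variant.cds_pos - 1  # 1-based CDS position -> 0-based region space
    for start, end, label in regions.regions:
        if start <= idx < end:
            return label
    raise AssertionError("region set does not partition the CDS")


def profile_similarity(a: RegionSet, b: RegionSet) -> float:
    """Percentage of CDS positions whose LDR/HDR label agrees."""
    if a.cds_length != b.cds_length:
        raise ValueError(
            f"CDS lengths differ: {a.cds_length} vs {b.cds_length}"
        )
    agree = int(np.sum(a.label_array() == b.label_array()))
    return 100.0 * agree / a.cds_length


def region_bed_rows(regions: RegionSet, profile: DensityProfile):
    """Rows for BED6 export: (start, end, label, mean window density)."""
    rows = []
    for start, end, label in regions.regions:
        rows.append((start, end, label, float(profile.density[start:end].mean())))
    return rows
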