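"""Core domain types: variants, genes, control genes and cohorts.

Conventions
-----------
* Genomic positions are 1-based (HGVS ``g.`` style); exported BED intervals
  are 0-based half-open.
* A population in which a variant is absent is stored as ``AC=0`` with that
  population's allele number, not as missing: absence from a frequency
  database is evidence of frequency zero at the surveyed allele number.
* When only a rounded allele frequency is available, the implied allele
  count ``AF * AN`` is kept as a real number by default.  Integer
  reconstruction (``round(AF * AN)``) is applied only where a discrete test
  requires counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .populations import PopulationLabel


@dataclass(frozen=True)
class PopFrequency:
    """Per-population frequency data at one site.

    Either ``af`` or ``ac`` may be absent (``None``); ``an`` is always
    known (site override or ``2 * n_individuals``).
    """

    an: int
    af: float | None = None
    ac: int | None = None

    def __post_init__(self) -> None:
        if self.an <= 0:
            raise ValueError(f"AN must be positive, got {self.an}")
        if self.af is None and self.ac is None:
            raise ValueError("at least one of AF and AC must be given")
        if self.ac is not None:
            if self.ac < 0:
                raise ValueError(f"AC must be >= 0, got {self.ac}")
            if self.ac > self.an:
                raise ValueError(f"AC={self.ac} exceeds AN={self.an}")
        if self.af is not None and not 0.0 <= self.af <= 1.0:
            raise ValueError(f"AF must lie in [0, 1], got {self.af}")
        if self.af is not None and self.ac is not None:
            # Allow for AF rounding: the printed AF must be within half a
            # count of AC/AN.
            if abs(self.af - self.ac / self.an) > 0.5 / self.an + 1e-12:
                raise ValueError(
                    f"inconsistent AF={self.af} vs AC/AN={self.ac}/{self.an}"
                )

    @property
    def frequency(self) -> float:
        """AF as given, else AC/AN."""
        if self.af is not None:
            return self.af
        return self.ac / self.an  # type: ignore[operator]

    @property
    def count(self) -> float:
        """Allele count: AC when known, otherwise the real-valued AF*AN."""
        if self.ac is not None:
            return float(self.ac)
        return self.af * self.an  # type: ignore[operator]


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site with per-population and optional cohort counts."""

    contig: str
    pos: int
    ref: str
    alt: str
    per_pop: dict[str, PopFrequency] = field(default_factory=dict)
    rsid: str | None = None
    consequence: str | None = None
    cds_pos: int | None = None
    cohort_ac: int | None = None
    cohort_an: int | None = None

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"pos must be strictly positive, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError(f"{self.key}: ref and alt must be non-empty")
        if self.cohort_ac is not None:
            if self.cohort_an is None or self.cohort_an <= 0:
                raise ValueError(f"{self.key}: cohort_ac without positive cohort_an")
            if self.cohort_ac < 0 or self.cohort_ac > self.cohort_an:
                raise ValueError(
                    f"{self.key}: cohort_ac={self.cohort_ac} outside "
                    f"[0, cohort_an={self.cohort_an}]"
                )

    @property
    def key(self) -> str:
        return f"{self.contig}:g.{self.pos}{self.ref}>{self.alt}"

    def af(self, code: str) -> float:
        """Allele frequency in a population; absent populations are 0."""
        pf = self.per_pop.get(code)
        return 0.0 if pf is None else pf.frequency

    def has_population(self, code: str) -> bool:
        return code in self.per_pop

    def with_cohort(self, ac: int, an: int) -> "VariantRecord":
        return replace(self, cohort_ac=ac, cohort_an=an)


@dataclass(frozen=True)
class GeneModel:
    """A transcript's coding sequence: intervals and total CDS length.

    ``cds_intervals`` are 0-based half-open genomic intervals, sorted and
    non-overlapping; ``cds_length`` must equal their total span.
    """

    gene_symbol: str
    transcript_id: str
    cds_intervals: tuple[tuple[str, int, int], ...]
    cds_length: int

    def __post_init__(self) -> None:
        total = 0
        prev_end: int | None = None
        prev_contig: str | None = None
        for contig, start, end in self.cds_intervals:
            if end <= start:
                raise ValueError(f"empty/inverted CDS interval {start}-{end}")
            if prev_contig == contig and prev_end is not None and start < prev_end:
                raise ValueError("CDS intervals overlap or are unsorted")
            total += end - start
            prev_end, prev_contig = end, contig
        if total != self.cds_length:
            raise ValueError(
                f"cds_length={self.cds_length} does not match interval "
                f"total {total}"
            )


def single_interval_gene(
    gene_symbol: str, cds_length: int, contig: str = "chr11", start: int = 0,
    transcript_id: str | None = None,
) -> GeneModel:
    """Convenience constructor for a gene modeled as one CDS block."""
    return GeneModel(
        gene_symbol=gene_symbol,
        transcript_id=transcript_id or f"{gene_symbol}-tx",
        cds_intervals=((contig, start, start + cds_length),),
        cds_length=cds_length,
    )


@dataclass(frozen=True)
class ControlGeneEntry:
    """A CDS-length-matched control gene with per-population variant counts."""

    gene_symbol: str
    cds_length: int
    rare_missense_count: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cds_length <= 0:
            raise ValueError(f"{self.gene_symbol}: cds_length must be positive")
        for code, count in self.rare_missense_count.items():
            if count < 0:
                raise ValueError(f"{self.gene_symbol}/{code}: negative count")

    def count(self, code: str) -> int:
        return self.rare_missense_count.get(code, 0)


@dataclass(frozen=True)
class CohortTable:
    """Rare missense variants observed in a sequenced cohort.

    Every variant carries cohort allele counts out of ``2 * n_probands``
    alleles, and passes the reference-population rarity filter.
    """

    variants: tuple[VariantRecord, ...]
    n_probands: int
    reference_population: str
    af_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.n_probands <= 0:
            raise ValueError(f"n_probands must be positive, got {self.n_probands}")
        an = 2 * self.n_probands
        for v in self.variants:
            if v.cohort_an != an:
                raise ValueError(
                    f"{v.key}: cohort_an={v.cohort_an}, expected 2*n_probands={an}"
                )
            if v.af(self.reference_population) >= self.af_threshold:
                raise ValueError(
                    f"{v.key}: {self.reference_population} AF "
                    f"{v.af(self.reference_population)} not below "
                    f"threshold {self.af_threshold}"
                )

    @property
    def cohort_an(self) -> int:
        return 2 * self.n_probands

    @property
    def aggregated_ac(self) -> int:
        return sum(v.cohort_ac or 0 for v in self.variants)


MISSENSE = "missense"


def filter_rare_missense(
    records: list[VariantRecord],
    reference: str | PopulationLabel = "NFE",
    af_threshold: float = 0.01,
) -> CohortTable:
    """Keep missense records rarer than ``af_threshold`` in the reference.

    The rarity comparison is strict (``AF < threshold``); a record absent
    from the reference population counts as frequency zero and is kept.
    Ordering is preserved, so the operation is idempotent.
    """
    if not 0.0 < af_threshold <= 1.0:
        raise ValueError(f"af_threshold must lie in (0, 1], got {af_threshold}")
    code = reference.code if isinstance(reference, PopulationLabel) else reference
    kept = tuple(
        r
        for r in records
        if r.consequence == MISSENSE and r.af(code) < af_threshold
    )
    if not kept:
        raise ValueError("no record passed the rare-missense filter")
    ans = {r.cohort_an for r in kept}
    if len(ans) != 1 or None in ans:
        raise ValueError("records must share one cohort allele number (2N)")
    (an,) = ans
    return CohortTable(
        variants=kept,
        n_probands=an // 2,  # type: ignore[operator]
        reference_population=code,
        af_threshold=af_threshold,
    )
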