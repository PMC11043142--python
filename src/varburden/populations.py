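"""Population panels and diploid sample sizes.

A *panel* maps a population code (``"NFE"``, ``"AFR"``, ...) to a
:class:`PopulationLabel` carrying its diploid sample size.  Allele numbers
default to ``2 * n_individuals``; per-site AN overrides on a variant record
take precedence when present.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PopulationLabel:
    """A named population with its diploid sample size."""

    code: str
    n_individuals: int

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("population code must be a non-empty string")
        if self.n_individuals <= 0:
            raise ValueError(
                f"population {self.code!r}: n_individuals must be positive, "
                f"got {self.n_individuals}"
            )

    @property
    def allele_number(self) -> int:
        """Default allele number: two alleles per diploid individual."""
        return 2 * self.n_individuals


def make_panel(sizes: dict[str, int]) -> dict[str, PopulationLabel]:
    """Build a panel from a ``code -> n_individuals`` mapping."""
    return {code: PopulationLabel(code, n) for code, n in sizes.items()}


#: gnomAD v2.1 exome diploid sample sizes for the continental populations
#: used throughout: non-Finnish European, African/African-American,
#: East Asian, South Asian, Latino/Admixed American, and the full release.
GNOMAD_V21_EXOMES: dict[str, PopulationLabel] = make_panel(
    {
        "NFE": 56_885,
        "AFR": 8_128,
        "EAS": 9_197,
        "SAS": 15_308,
        "AMR": 17_296,
        "GLOBAL": 125_748,
    }
)

#: Sentinel population code under which a cohort's own allele counts
#: (``cohort_ac / cohort_an``) are addressed in two-group comparisons.
COHORT_CODE = "FMD"
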