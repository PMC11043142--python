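"""Pairwise linkage disequilibrium r² from haplotypes or genotypes.

For two biallelic loci with haplotype frequency ``p_AB`` and allele
frequencies ``p_A``, ``p_B``,

    D  = p_AB - p_A * p_B
    r² = D² / (p_A * (1 - p_A) * p_B * (1 - p_B)).

Phased haplotypes give ``p_AB`` by counting.  Unphased diploid dosages
leave the double heterozygote ambiguous (AB/ab vs Ab/aB); the standard
two-locus EM algorithm resolves it by maximum likelihood under random
mating, starting from linkage equilibrium.  r² is invariant under allele
relabeling at either locus, and equals 1 exactly when only two of the
four haplotypes segregate with matching frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Returned where r² is undefined (a monomorphic locus).
UNDEFINED = math.nan


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid dosages (individuals x variants), optionally phased."""

    individuals: tuple[str, ...]
    variant_ids: tuple[str, ...]
    dosages: np.ndarray  # shape (n_individuals, n_variants), values 0/1/2
    phased_haplotypes: np.ndarray | None = None  # (2*n_individuals, n_variants)

    def __post_init__(self) -> None:
        n, v = self.dosages.shape
        if n != len(self.individuals) or v != len(self.variant_ids):
            raise ValueError("dosage matrix shape does not match labels")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")
        if self.phased_haplotypes is not None:
            h = self.phased_haplotypes
            if h.shape != (2 * n, v):
                raise ValueError("phased haplotype matrix shape mismatch")
            if (h[0::2] + h[1::2] != self.dosages).any():
                raise ValueError("haplotype sums disagree with dosages")


@dataclass(frozen=True)
class LDMatrix:
    variant_ids: tuple[str, ...]
    r2: np.ndarray  # symmetric, unit diagonal, NaN where undefined
    n_used: np.ndarray  # per-pair informative sample size


def _r2_from_freqs(p_ab: float, p_a: float, p_b: float) -> float:
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return UNDEFINED
    d = p_ab - p_a * p_b
    return min(1.0, (d * d) / denom)


def r2_phased(h1: np.ndarray, h2: np.ndarray) -> float:
    """r² from two phased haplotype columns (0/1 per haplotype).

    Computed in integer arithmetic, so a sample in which only two of the
    four haplotypes segregate returns exactly 1.  Monomorphic input
    leaves r² undefined and returns NaN (a flagged missing value,
    deliberately distinct from 0).
    """
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    if h1.shape != h2.shape or h1.ndim != 1 or len(h1) < 2:
        raise ValueError("need two equal-length columns of >= 2 haplotypes")
    if not (np.isin(h1, (0, 1)).all() and np.isin(h2, (0, 1)).all()):
        raise ValueError("haplotype columns must be binary")
    h1 = h1.astype(np.int64)
    h2 = h2.astype(np.int64)
    n = len(h1)
    n_a = int(h1.sum())
    n_b = int(h2.sum())
    n_ab = int((h1 & h2).sum())
    denom = n_a * (n - n_a) * n_b * (n - n_b)
    if denom == 0:
        return UNDEFINED
    d_num = n * n_ab - n_a * n_b  # n^2 * D, exactly
    return min(1.0, (d_num * d_num) / denom)


def r2_unphased_em(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> float:
    """r² from two unphased dosage columns via two-locus EM.

    Equals :func:`r2_phased` on the underlying haplotypes whenever the
    sample contains no double heterozygote (phase then being unambiguous).
    Missing dosages are not allowed.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise ValueError("dosage columns must share one length")
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (g1, g2), 1)
    return _em_from_genotype_table(table, tol=tol, max_iter=max_iter)


def _em_from_genotype_table(
    table: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> float:
    """EM over haplotype frequencies given the 3x3 genotype count table."""
    n = int(table.sum())
    if n == 0:
        raise ValueError("empty genotype table")
    # Haplotype counts contributed unambiguously (in haplotype units):
    # genotype (i, j) carries i copies of allele A and j of allele B.
    g = table.astype(float)
    p_a = float((g * np.arange(3)[:, None]).sum()) / (2 * n)
    p_b = float((g * np.arange(3)[None, :]).sum()) / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return UNDEFINED

    # Fixed contributions to haplotype counts (AB, Ab, aB, ab) from the
    # eight unambiguous genotype cells.
    fixed = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if (i, j) == (1, 1):
                continue
            fixed += g[i, j] * _unambiguous_haplotypes(i, j)
    dh = g[1, 1]  # double heterozygotes

    freqs = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                      (1 - p_a) * (1 - p_b)])
    for _ in range(max_iter):
        # E-step: split double heterozygotes between AB/ab and Ab/aB.
        cis = freqs[0] * freqs[3]
        trans = freqs[1] * freqs[2]
        total = cis + trans
        w = 0.5 if total == 0 else cis / total
        counts = fixed.copy()
        counts[0] += dh * w
        counts[3] += dh * w
        counts[1] += dh * (1 - w)
        counts[2] += dh * (1 - w)
        new = counts / (2 * n)
        delta = float(np.abs(new - freqs).max())
        freqs = new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"EM did not converge after {max_iter} iterations "
            f"(last delta {delta:.3e})"
        )
    # Boundary MLE: when no unambiguous repulsion (or coupling) haplotype
    # was seen and EM drove the ambiguous mass to the same side, only two
    # haplotypes segregate and r² is identically 1.
    if fixed[1] == 0 and fixed[2] == 0 and freqs[1] + freqs[2] < 1e-8:
        return 1.0
    if fixed[0] == 0 and fixed[3] == 0 and freqs[0] + freqs[3] < 1e-8:
        return 1.0
    return _r2_from_freqs(freqs[0], p_a, p_b)


def _unambiguous_haplotypes(i: int, j: int) -> np.ndarray:
    """Haplotype counts (AB, Ab, aB, ab) for a non-(1,1) genotype cell."""
    # Alleles at locus 1: i copies of A over two haplotypes; same for B.
    # With at most one heterozygous locus, phase is determined.
    hap = np.zeros(4)
    a_alleles = [1] * i + [0] * (2 - i)
    b_alleles = [1] * j + [0] * (2 - j)
    # Pair the A alleles with B alleles; when one locus is homozygous any
    # pairing is equivalent.
    for a, b in zip(a_alleles, b_alleles):
        hap[(1 - a) * 2 + (1 - b)] += 1
    return hap


def ld_matrix(genotypes: GenotypeMatrix, tol: float = 1e-10, max_iter: int = 1000) -> LDMatrix:
    """All-pairs r² matrix (phased closed form when phase is available).

    Pairs involving a monomorphic variant are NaN (flagged missing); the
    diagonal of polymorphic variants is 1.
    """
    n_var = len(genotypes.variant_ids)
    if n_var < 1:
        raise ValueError("need at least one variant")
    r2 = np.full((n_var, n_var), UNDEFINED)
    n_ind = len(genotypes.individuals)
    n_used = np.full((n_var, n_var), n_ind, dtype=np.int64)
    phased = genotypes.phased_haplotypes
    poly = [
        len(np.unique(genotypes.dosages[:, k])) > 1 for k in range(n_var)
    ]
    for i in range(n_var):
        if poly[i]:
            r2[i, i] = 1.0
        for j in range(i + 1, n_var):
            if not (poly[i] and poly[j]):
                continue
            if phased is not None:
                value = r2_phased(phased[:, i], phased[:, j])
            else:
                value = r2_unphased_em(
                    genotypes.dosages[:, i], genotypes.dosages[:, j],
                    tol=tol, max_iter=max_iter,
                )
            r2[i, j] = r2[j, i] = value
    return LDMatrix(variant_ids=genotypes.variant_ids, r2=r2, n_used=n_used)


def max_feasible_r2(p_a: float, p_b: float) -> float:
    """Largest r² attainable for positive D at the given minor AFs."""
    q_a, q_b = 1 - p_a, 1 - p_b
    return min((p_a * q_b) / (q_a * p_b), (q_a * p_b) / (p_a * q_b))
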