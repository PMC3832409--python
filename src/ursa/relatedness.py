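"""Pairwise relatedness and parent-offspring exclusion.

Implements the Lynch-Ritland method-of-moments relatedness estimator for
biallelic loci.  With reference individual x carrying alleles (a, b) and
proband y carrying (c, d), the per-locus components are

    N_l = p_a (S_bc + S_bd) + p_b (S_ac + S_ad) - 4 p_a p_b
    D_l = (1 + S_ab)(p_a + p_b) - 4 p_a p_b

where S_uv = 1 iff alleles u and v are identical in state and p_a is the
population frequency of allele a.  The multilocus estimate is the ratio of
sums r_{x->y} = sum_l N_l / sum_l D_l - which weights loci by their
denominators, as the source estimator prescribes, and removes the
singularity of a heterozygous reference at p = 1/2 - symmetrized over the
two choices of reference.  E[N_l] = 0 for unrelated pairs under
Hardy-Weinberg proportions, and E[r] equals the relatedness coefficient
(0.5 parent-offspring or full sibs, 0.25 half sibs).

Parent-offspring exclusion is Mendelian: a true parent and offspring share
at least one allele identical by descent at every autosomal locus, so a
single opposite-homozygote locus (AA vs BB) excludes the relationship.
X-linked loci add power via the asymmetric inheritance of the X: sons
receive their single X from the mother, daughters one X from each parent.

Genotype calls are strings as in :mod:`ursa.panel_stats`; allele
frequencies are frequencies of allele ``A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_stats import (
    DIPLOID_CALLS,
    MISSING,
    GenotypeMatrix,
    assign_mtdna_haplotype,
)

__all__ = [
    "allele_freqs",
    "lr_locus_components",
    "lynch_ritland_r",
    "pair_r",
    "bootstrap_ci",
    "candidate_first_order",
    "po_exclusion_autosomal",
    "po_exclusion_x",
    "classify_dyads",
    "DyadReport",
    "opposite_homozygote_mask",
]

POSSIBLE = "Possible"
EXCLUDED = "Excluded"
KNOWN = "Known"


@dataclass(frozen=True)
class DyadReport:
    """One row of the relatedness report for a candidate first-order dyad."""

    ind1: str
    ind2: str
    sexes: str  # e.g. "M-F"
    haplotype: str | None  # shared mtDNA haplotype, or "mismatch"
    r: float
    ci_low: float
    ci_high: float
    po_status: str  # Known | Possible | Excluded
    excluding_loci: tuple[str, ...] = ()


def allele_freqs(
    matrix: GenotypeMatrix, loci: Sequence[str] | None = None
) -> dict[str, float]:
    """Frequency of allele A per locus, pooling diploid and haploid calls."""
    if loci is None:
        loci = matrix.loci
    freqs = {}
    for locus in loci:
        nA = nB = 0
        for call in matrix.calls[locus]:
            if call == MISSING:
                continue
            nA += call.count("A")
            nB += call.count("B")
        if nA + nB == 0:
            raise ValueError(f"locus {locus} entirely missing")
        freqs[locus] = nA / (nA + nB)
    return freqs


def lr_locus_components(
    x_genotype: str, y_genotype: str, p_A: float
) -> tuple[float, float]:
    """Single-locus numerator and denominator with x as reference."""
    if len(x_genotype) != 2 or len(y_genotype) != 2:
        raise ValueError("diploid genotypes required")
    freq = {"A": p_A, "B": 1.0 - p_A}
    a, b = x_genotype
    c, d = y_genotype
    pa, pb = freq[a], freq[b]
    S = lambda u, v: 1.0 if u == v else 0.0
    N = pa * (S(b, c) + S(b, d)) + pb * (S(a, c) + S(a, d)) - 4 * pa * pb
    D = (1 + S(a, b)) * (pa + pb) - 4 * pa * pb
    return N, D


def _lr_nd_arrays(
    gx: np.ndarray, gy: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (N_l, D_l) with x as reference, from A-allele counts."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    case = gx * 3 + gy  # gx, gy in {0,1,2}
    hom_D = 4 * p * q
    het_D = 1 - 4 * p * q
    N = np.select(
        [case == 8, case == 7, case == 6,  # x = AA
         case == 5, case == 4, case == 3,  # x = AB
         case == 2, case == 1, case == 0],  # x = BB
        [4 * p * q, 2 * p * (1 - 2 * p), -4 * p**2,
         2 * q * (1 - 2 * p), het_D, 2 * p * (2 * p - 1),
         -4 * q**2, 2 * q * (1 - 2 * q), 4 * p * q],
    )
    D = np.where(gx == 1, het_D, hom_D)
    return N, D


def _usable(
    x_calls: Mapping[str, str],
    y_calls: Mapping[str, str],
    freqs: Mapping[str, float],
    loci: Sequence[str] | None,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    if loci is None:
        loci = list(freqs)
    code = {"AA": 2, "AB": 1, "BB": 0}
    used, gx, gy, p = [], [], [], []
    for locus in loci:
        cx, cy = x_calls.get(locus, MISSING), y_calls.get(locus, MISSING)
        if cx not in DIPLOID_CALLS or cy not in DIPLOID_CALLS:
            continue
        pl = freqs[locus]
        if not 0 < pl < 1:
            continue  # monomorphic loci carry no information
        used.append(locus)
        gx.append(code[cx])
        gy.append(code[cy])
        p.append(pl)
    return used, np.array(gx), np.array(gy), np.array(p)


def pair_r(gx: np.ndarray, gy: np.ndarray, p: np.ndarray) -> float:
    """Symmetrized ratio-of-sums Lynch-Ritland r from coded genotypes."""
    Nx, Dx = _lr_nd_arrays(gx, gy, p)
    Ny, Dy = _lr_nd_arrays(gy, gx, p)
    sums = []
    for N, D in ((Nx, Dx), (Ny, Dy)):
        sd = D.sum()
        if sd != 0:
            sums.append(N.sum() / sd)
    if not sums:
        raise ValueError("relatedness undefined: zero denominator both directions")
    return float(np.mean(sums))


def lynch_ritland_r(
    x_calls: Mapping[str, str],
    y_calls: Mapping[str, str],
    freqs: Mapping[str, float],
    loci: Sequence[str] | None = None,
) -> float:
    """Multilocus Lynch-Ritland r between two individuals.

    Loci with a missing call in either individual, or monomorphic in
    ``freqs``, are dropped.  The estimate is the ratio of summed numerators
    to summed denominators, averaged over the two choices of reference
    individual.
    """
    used, gx, gy, p = _usable(x_calls, y_calls, freqs, loci)
    if not used:
        raise ValueError("no usable loci for this dyad")
    return pair_r(gx, gy, p)


def bootstrap_ci(
    x_calls: Mapping[str, str],
    y_calls: Mapping[str, str],
    freqs: Mapping[str, float],
    loci: Sequence[str] | None = None,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap (2.5/97.5) of r, resampling loci with replacement."""
    used, gx, gy, p = _usable(x_calls, y_calls, freqs, loci)
    if len(used) < 2:
        raise ValueError("need at least two usable loci for a bootstrap")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    Nx, Dx = _lr_nd_arrays(gx, gy, p)
    Ny, Dy = _lr_nd_arrays(gy, gx, p)
    L = len(used)
    idx = rng.integers(0, L, size=(reps, L))
    with np.errstate(divide="ignore", invalid="ignore"):
        rx = Nx[idx].sum(axis=1) / Dx[idx].sum(axis=1)
        ry = Ny[idx].sum(axis=1) / Dy[idx].sum(axis=1)
        r_rep = np.nanmean(np.vstack([rx, ry]), axis=0)
    r_rep = r_rep[np.isfinite(r_rep)]
    if r_rep.size == 0:
        raise ValueError("all bootstrap replicates degenerate")
    lo, hi = np.percentile(r_rep, [2.5, 97.5])
    return float(lo), float(hi)


def _row_calls(matrix: GenotypeMatrix, ind: str) -> dict[str, str]:
    return matrix.calls.loc[ind].to_dict()


def candidate_first_order(
    matrix: GenotypeMatrix,
    freqs: Mapping[str, float] | None = None,
    threshold: float = 0.40,
    loci: Sequence[str] | None = None,
) -> list[tuple[str, str, float]]:
    """All unordered dyads with r above the first-order screening threshold.

    True first-order relatives (parent-offspring, full sibs) have r = 0.5;
    screening at r > 0.40 keeps them with margin for sampling noise.
    """
    if len(matrix.individuals) < 2:
        raise ValueError("need at least two individuals")
    if loci is None:
        loci = matrix.loci_of_class("autosomal")
    if freqs is None:
        freqs = allele_freqs(matrix, loci)
    rows = {i: _row_calls(matrix, i) for i in matrix.individuals}
    out = []
    for i, j in combinations(matrix.individuals, 2):
        r = lynch_ritland_r(rows[i], rows[j], freqs, loci)
        if r > threshold:
            out.append((i, j, r))
    return out


def opposite_homozygote_mask(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Boolean mask of loci where the pair are opposite homozygotes.

    Codes are A-allele counts with negatives meaning missing; missing calls
    never exclude.
    """
    return ((gx == 2) & (gy == 0)) | ((gx == 0) & (gy == 2))


def po_exclusion_autosomal(
    x_calls: Mapping[str, str],
    y_calls: Mapping[str, str],
    loci: Sequence[str],
) -> tuple[str, list[str]]:
    """Exclude parent-offspring if any locus shows opposite homozygotes.

    A parent transmits one allele to its offspring, so a true
    parent-offspring dyad shares at least one allele at every locus;
    AA vs BB at any locus is therefore excluding.  Missing calls never
    exclude.
    """
    excluding = [
        locus
        for locus in loci
        if {x_calls.get(locus), y_calls.get(locus)} == {"AA", "BB"}
    ]
    return (EXCLUDED if excluding else POSSIBLE), excluding


def _x_alleles(call: str, sex: str) -> str | None:
    """Normalise an X-locus call to its allele string; None if missing."""
    if call == MISSING:
        return None
    if sex == "M":
        alleles = set(call)
        if len(alleles) != 1:
            raise ValueError(f"heterozygous X call {call!r} for a male")
        return alleles.pop()
    return call if len(call) == 2 else call * 2


def _x_parent_compatible(
    parent_sex: str, parent: str | None, child_sex: str, child: str | None
) -> bool:
    """Can ``parent`` be the parent of ``child`` at one X locus?"""
    if parent is None or child is None:
        return True
    if parent_sex == "F" and child_sex == "M":
        return child in parent  # son's single X is maternal
    if parent_sex == "F" and child_sex == "F":
        return bool(set(parent) & set(child))
    if parent_sex == "M" and child_sex == "F":
        return parent in child  # daughter carries the paternal X
    return True  # father-son: no paternal X transmission


def po_exclusion_x(
    sex1: str,
    x_calls1: Mapping[str, str],
    sex2: str,
    x_calls2: Mapping[str, str],
    loci: Sequence[str],
) -> str:
    """Exclude parent-offspring via X-chromosome inheritance rules.

    Sons inherit their single X from the mother; daughters inherit one X
    from each parent.  The dyad is unordered, so it is excluded only when
    neither individual could be the other's parent: a father-son pair is
    never excludable this way, while e.g. mother AA with son B fails both
    orderings.  Unknown sex never excludes; a heterozygous male X call is a
    data inconsistency.
    """
    if sex1 not in ("M", "F") or sex2 not in ("M", "F"):
        return POSSIBLE
    a1 = {l: _x_alleles(x_calls1.get(l, MISSING), sex1) for l in loci}
    a2 = {l: _x_alleles(x_calls2.get(l, MISSING), sex2) for l in loci}
    one_parent_ok = all(
        _x_parent_compatible(sex1, a1[l], sex2, a2[l]) for l in loci
    )
    two_parent_ok = all(
        _x_parent_compatible(sex2, a2[l], sex1, a1[l]) for l in loci
    )
    return POSSIBLE if (one_parent_ok or two_parent_ok) else EXCLUDED


def classify_dyads(
    matrix: GenotypeMatrix,
    freqs: Mapping[str, float] | None = None,
    known_po: Sequence[tuple[str, str]] | None = None,
    threshold: float = 0.40,
    reps: int = 1000,
    seed: int = 0,
) -> list[DyadReport]:
    """Screen, estimate and classify candidate first-order dyads.

    Dyads with r above ``threshold`` get a bootstrap CI, autosomal
    allele-sharing exclusion and X-inheritance exclusion; survivors are
    labelled Known (if listed in ``known_po``) or Possible.  Reports are
    sorted by individual ids.
    """
    aut = matrix.loci_of_class("autosomal")
    x_loci = matrix.loci_of_class("X")
    mt_loci = matrix.loci_of_class("mtDNA")
    if freqs is None:
        freqs = allele_freqs(matrix, aut)
    known = {frozenset(d) for d in (known_po or [])}
    rng = np.random.default_rng(seed)
    reports = []
    for i, j, r in candidate_first_order(matrix, freqs, threshold, aut):
        xi, xj = _row_calls(matrix, i), _row_calls(matrix, j)
        lo, hi = bootstrap_ci(xi, xj, freqs, aut, reps=reps, seed=rng)
        status, excl = po_exclusion_autosomal(xi, xj, aut)
        if status != EXCLUDED and x_loci:
            status = po_exclusion_x(
                matrix.sex[i], xi, matrix.sex[j], xj, x_loci
            )
            if status == EXCLUDED:
                excl = []
        if status != EXCLUDED and frozenset((i, j)) in known:
            status = KNOWN
        hap = None
        if len(mt_loci) == 4:
            h1 = assign_mtdna_haplotype([xi[l] for l in mt_loci])
            h2 = assign_mtdna_haplotype([xj[l] for l in mt_loci])
            hap = h1 if h1 == h2 else "mismatch"
        reports.append(
            DyadReport(
                ind1=i,
                ind2=j,
                sexes=f"{matrix.sex[i]}-{matrix.sex[j]}",
                haplotype=hap,
                r=r,
                ci_low=lo,
                ci_high=hi,
                po_status=status,
                excluding_loci=tuple(excl),
            )
        )
    return sorted(reports, key=lambda d: (d.ind1, d.ind2))
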