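"""Locus statistics and panel selection for a biallelic SNP chip.

Covers per-locus descriptive statistics (allele frequencies, observed and
expected heterozygosity), the conditional exact test of Hardy-Weinberg
equilibrium, pairwise linkage disequilibrium (D') estimated by EM from
unphased diploid genotypes, detection of X-linked loci from the
all-males-homozygous signature together with its Type-I-error probability,
mitochondrial haplotype assignment, Y-marker sex calls, and MAF-ranked
selection of the final panel.

Genotype calls are strings: diploid ``AA``/``AB``/``BB``, haploid (or
hemizygous) ``A``/``B``, missing ``--``.  Allele frequencies are expressed
for allele ``A``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "LocusStats",
    "PanelSpec",
    "MonomorphicLocusError",
    "locus_stats",
    "hwe_exact",
    "ld_dprime",
    "dprime_from_codes",
    "flag_linked_pairs",
    "detect_x_linked",
    "x_typeI_error",
    "assign_mtdna_haplotype",
    "determine_sex",
    "select_panel",
]

DIPLOID_CALLS = frozenset({"AA", "AB", "BB"})
HAPLOID_CALLS = frozenset({"A", "B"})
MISSING = "--"
LOCUS_CLASSES = frozenset({"autosomal", "X", "mtDNA", "Y"})
HAPLOID_CLASSES = frozenset({"mtDNA", "Y"})

#: printed haplotype key at the four mitochondrial markers
#: (Ua03mt, Ua04mt, Ua05mt, Ua07mt) -> lineage label
MTDNA_HAPLOTYPES = {"ABAA": "NorthA", "AAAA": "NorthB", "BBBB": "South"}

#: call string -> count of allele A (diploid scale); -1 = missing
CODE_OF_CALL = {"AA": 2, "AB": 1, "BB": 0, "--": -1}


class MonomorphicLocusError(ValueError):
    """Raised where a statistic is undefined for a fixed locus."""


class GenotypeMatrix:
    """Individuals x loci biallelic genotype calls with sample/locus metadata.

    Parameters
    ----------
    calls : DataFrame of call strings, index = individual ids, columns = loci.
    sex : mapping individual -> {"M", "F", "unknown"}.
    locus_class : mapping locus -> {"autosomal", "X", "mtDNA", "Y"}.
    group : optional mapping individual -> subpopulation label.
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        sex: Mapping[str, str],
        locus_class: Mapping[str, str],
        group: Mapping[str, str] | None = None,
    ) -> None:
        self.calls = calls.astype(str)
        self.sex = {i: sex.get(i, "unknown") for i in calls.index}
        self.locus_class = dict(locus_class)
        self.group = dict(group) if group is not None else {}
        self._validate()

    def _validate(self) -> None:
        missing_meta = [l for l in self.calls.columns if l not in self.locus_class]
        if missing_meta:
            raise ValueError(f"loci without class metadata: {missing_meta}")
        bad_class = set(self.locus_class.values()) - LOCUS_CLASSES
        if bad_class:
            raise ValueError(f"unknown locus classes: {bad_class}")
        if set(self.sex.values()) - {"M", "F", "unknown"}:
            raise ValueError("sex must be M, F or unknown")
        valid = DIPLOID_CALLS | HAPLOID_CALLS | {MISSING}
        for locus in self.calls.columns:
            cls = self.locus_class[locus]
            col = self.calls[locus]
            for ind, call in col.items():
                if call not in valid:
                    raise ValueError(f"invalid call {call!r} at ({ind}, {locus})")
                if cls in HAPLOID_CLASSES and call in DIPLOID_CALLS:
                    raise ValueError(
                        f"diploid call {call} at haploid locus ({ind}, {locus})"
                    )
                if cls == "X" and call == "AB" and self.sex.get(ind) == "M":
                    raise ValueError(
                        f"heterozygous X call for male at ({ind}, {locus})"
                    )

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    def loci_of_class(self, cls: str) -> list[str]:
        return [l for l in self.calls.columns if self.locus_class[l] == cls]

    def codes(self, loci: Sequence[str] | None = None) -> np.ndarray:
        """Diploid A-allele counts (0/1/2), -1 for missing or haploid calls."""
        sub = self.calls if loci is None else self.calls.loc[:, list(loci)]
        return (
            sub.apply(lambda col: col.map(lambda c: CODE_OF_CALL.get(c, -1)))
            .to_numpy(dtype=np.int8)
        )

    def subset(self, individuals: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.loc[list(individuals)],
            {i: self.sex[i] for i in individuals},
            self.locus_class,
            {i: self.group[i] for i in individuals if i in self.group},
        )


@dataclass(frozen=True)
class LocusStats:
    locus: str
    p: float  # major allele frequency
    maf: float
    Ho: float
    He: float
    hwe_p: float | None
    n_called: int


@dataclass(frozen=True)
class PanelSpec:
    target_size: int = 96
    reserved: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "reserved", tuple(self.reserved))
        if self.target_size < len(self.reserved):
            raise ValueError("target_size smaller than reserved set")


def _allele_counts(calls: Iterable[str]) -> tuple[int, int, dict[str, int]]:
    """(nA, nB, diploid genotype counts) pooling diploid and haploid calls."""
    nA = nB = 0
    dip = {"AA": 0, "AB": 0, "BB": 0}
    for c in calls:
        if c == MISSING:
            continue
        if c in DIPLOID_CALLS:
            dip[c] += 1
            nA += c.count("A")
            nB += c.count("B")
        elif c in HAPLOID_CALLS:
            nA += c == "A"
            nB += c == "B"
        else:
            raise ValueError(f"invalid call {c!r}")
    return nA, nB, dip


def locus_stats(matrix: GenotypeMatrix, locus: str) -> LocusStats:
    """Descriptive statistics for one locus.

    Allele counts pool diploid (2 alleles per call) and haploid (1 per call)
    contributions; observed heterozygosity and the HWE test use diploid calls
    only.  ``p`` is the major-allele frequency and He = 2 p (1-p).
    """
    col = matrix.calls[locus]
    nA, nB, dip = _allele_counts(col)
    n_alleles = nA + nB
    if n_alleles == 0:
        raise ValueError(f"locus {locus} has no called genotypes")
    fA = nA / n_alleles
    p = max(fA, 1 - fA)
    maf = 1 - p
    n_dip = sum(dip.values())
    Ho = dip["AB"] / n_dip if n_dip else 0.0
    He = 2 * p * (1 - p)
    hwe_p = hwe_exact(dip["AA"], dip["AB"], dip["BB"]) if n_dip else None
    n_called = int((col != MISSING).sum())
    return LocusStats(locus, p, maf, Ho, He, hwe_p, n_called)


def hwe_exact(nAA: int, nAB: int, nBB: int) -> float:
    """Exact test of Hardy-Weinberg proportions, conditional on allele counts.

    The p-value sums, over heterozygote counts compatible with the observed
    allele counts, the conditional probabilities of all genotype
    configurations no more probable than the observed one.
    """
    if min(nAA, nAB, nBB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = nAA + nAB + nBB
    if n < 1:
        raise ValueError("need at least one genotype")
    nA = 2 * nAA + nAB
    nB = 2 * n - nA
    lg = math.lgamma

    def log_prob(nab: int) -> float:
        naa = (nA - nab) // 2
        nbb = (nB - nab) // 2
        return (
            lg(n + 1)
            - lg(naa + 1)
            - lg(nab + 1)
            - lg(nbb + 1)
            + nab * math.log(2)
            + lg(nA + 1)
            + lg(nB + 1)
            - lg(2 * n + 1)
        )

    support = range(nA % 2, min(nA, nB) + 1, 2)
    probs = {nab: math.exp(log_prob(nab)) for nab in support}
    p_obs = probs[nAB]
    p = sum(pr for pr in probs.values() if pr <= p_obs * (1 + 1e-12))
    return min(p, 1.0)


def _em_haplotypes(
    counts: np.ndarray, tol: float = 1e-9, max_iter: int = 1000
) -> np.ndarray:
    """EM haplotype frequencies (hAB, hAb, haB, hab) from a 3x3 genotype table.

    ``counts[i, j]`` is the number of individuals with i copies of allele A
    at locus 1 and j copies at locus 2 (i, j counted from 2 down to 0 along
    AA/AB/BB order below).  Only the double heterozygote is phase ambiguous.
    Initialised at linkage equilibrium.
    """
    n = counts.sum()
    pA = (counts * np.array([2, 2, 2, 1, 1, 1, 0, 0, 0]).reshape(3, 3)).sum() / (2 * n)
    pB = (counts * np.array([2, 1, 0, 2, 1, 0, 2, 1, 0]).reshape(3, 3)).sum() / (2 * n)
    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    # haplotype pairs contributed unambiguously by the 8 phase-known cells:
    # index order: AB, Ab, aB, ab
    fixed = np.zeros(4)
    fixed[0] += 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    fixed[1] += 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    fixed[2] += 2 * counts[2, 0] + counts[1, 0] + counts[2, 1]
    fixed[3] += 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    n_dh = counts[1, 1]
    for _ in range(max_iter):
        num_cis = h[0] * h[3]
        num_trans = h[1] * h[2]
        tot = num_cis + num_trans
        w = num_cis / tot if tot > 0 else 0.5
        new = fixed + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= new.sum()
        if np.max(np.abs(new - h)) < tol:
            h = new
            break
        h = new
    return h


def dprime_from_codes(ga: np.ndarray, gb: np.ndarray) -> float:
    """D' between two loci from unphased diploid codes (A-allele counts).

    Pairs with a missing code (< 0) at either locus are dropped.  Haplotype
    frequencies come from EM; D = p_AB - p_A p_B is then normalised by its
    maximum attainable magnitude given the allele frequencies.
    """
    ok = (ga >= 0) & (gb >= 0)
    ga, gb = ga[ok], gb[ok]
    if ga.size < 2:
        raise ValueError("need at least two individuals called at both loci")
    counts = np.zeros((3, 3), dtype=float)
    for i, j in zip(ga, gb):
        counts[2 - i, 2 - j] += 1
    pA = ga.mean() / 2
    pB = gb.mean() / 2
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicLocusError("D' undefined for a monomorphic locus")
    h = _em_haplotypes(counts)
    D = h[0] - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax == 0:
        raise MonomorphicLocusError("D' undefined: zero Dmax")
    return abs(D) / dmax


def ld_dprime(matrix: GenotypeMatrix, locus_a: str, locus_b: str) -> float:
    """D' between two diploid loci of a genotype matrix."""
    codes = matrix.codes([locus_a, locus_b])
    return dprime_from_codes(codes[:, 0], codes[:, 1])


def flag_linked_pairs(
    matrix: GenotypeMatrix,
    threshold: float = 0.9,
    loci: Sequence[str] | None = None,
) -> list[tuple[str, str, float]]:
    """All unordered locus pairs with D' >= threshold, sorted descending.

    Defaults to the autosomal loci.  Pairs where D' is undefined
    (monomorphic, too few joint calls) are skipped.
    """
    if loci is None:
        loci = matrix.loci_of_class("autosomal")
    codes = matrix.codes(loci)
    out = []
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            try:
                dp = dprime_from_codes(codes[:, i], codes[:, j])
            except (MonomorphicLocusError, ValueError):
                continue
            if dp >= threshold:
                out.append((loci[i], loci[j], dp))
    return sorted(out, key=lambda t: (-t[2], t[0], t[1]))


def x_typeI_error(n_males: int, maf: float) -> float:
    """Probability that ``n_males`` males are all homozygous by chance.

    Under Hardy-Weinberg proportions at an autosomal locus with minor allele
    frequency ``maf``, each male is homozygous with probability
    ``maf^2 + (1-maf)^2``; the all-homozygous event has probability
    ``(maf^2 + (1-maf)^2) ** n_males``.  This is the Type-I-error chance of
    declaring a locus X-linked from the male-homozygosity signature.
    """
    if not 0 <= maf <= 0.5:
        raise ValueError("maf must lie in [0, 0.5]")
    if n_males < 0:
        raise ValueError("n_males must be non-negative")
    return (maf**2 + (1 - maf) ** 2) ** n_males


def detect_x_linked(
    matrix: GenotypeMatrix, loci: Sequence[str] | None = None
) -> list[tuple[str, float]]:
    """Flag loci showing the X-linkage signature, with Type-I-error chance.

    A polymorphic locus is flagged when every called male is homozygous (or
    hemizygous) for one and the same allele while at least one female is
    heterozygous - males carry a single X, so a truly X-linked SNP can never
    yield a heterozygous male.  Each flagged locus is returned with
    ``x_typeI_error(n_called_males, maf)``.
    """
    males = [i for i in matrix.individuals if matrix.sex[i] == "M"]
    females = [i for i in matrix.individuals if matrix.sex[i] == "F"]
    if not males or not females:
        raise ValueError("need sex annotations with at least one M and one F")
    if loci is None:
        loci = [
            l
            for l in matrix.loci
            if matrix.locus_class[l] in ("autosomal", "X")
        ]
    out = []
    for locus in loci:
        col = matrix.calls[locus]
        male_calls = [col[i] for i in males if col[i] != MISSING]
        female_calls = [col[i] for i in females if col[i] != MISSING]
        if not male_calls:
            continue
        male_alleles = {c[0] for c in male_calls}
        all_homozygous = all(len(set(c)) == 1 for c in male_calls)
        if not (all_homozygous and len(male_alleles) == 1):
            continue
        if not any(c == "AB" for c in female_calls):
            continue
        st = locus_stats(matrix, locus)
        if st.maf == 0:
            continue
        out.append((locus, x_typeI_error(len(male_calls), st.maf)))
    return out


def assign_mtdna_haplotype(calls: Sequence[str]) -> str:
    """Mitochondrial lineage from haploid calls at the four mtDNA markers.

    The marker order is Ua03mt, Ua04mt, Ua05mt, Ua07mt; ABAA -> NorthA,
    AAAA -> NorthB, BBBB -> South, anything else (including missing)
    -> unknown.
    """
    if len(calls) != 4:
        raise ValueError("expected calls at exactly four mtDNA markers")
    for c in calls:
        if c in DIPLOID_CALLS or (len(c) == 2 and c != MISSING):
            raise ValueError(f"diploid call {c!r} at a haploid mtDNA marker")
    key = "".join(calls)
    return MTDNA_HAPLOTYPES.get(key, "unknown")


def determine_sex(y_call1: str, y_call2: str) -> str:
    """Sex call from two monomorphic Y-chromosome markers.

    Y markers amplify in males only, so presence at both markers calls male,
    absence at both calls female, and a discordant pair is inconclusive.
    A missing call ("--") counts as absent.
    """
    present = [c not in (MISSING, "") for c in (y_call1, y_call2)]
    if all(present):
        return "M"
    if not any(present):
        return "F"
    return "inconclusive"


def select_panel(candidates: Sequence[LocusStats], spec: PanelSpec) -> list[str]:
    """Fill the panel: reserved markers first, then highest-MAF candidates.

    Ties break by He descending, then locus id ascending, so the output is
    deterministic and invariant to input order.
    """
    by_id = {c.locus: c for c in candidates}
    if len(by_id) != len(candidates):
        raise ValueError("duplicate locus ids among candidates")
    missing = [r for r in spec.reserved if r not in by_id]
    if missing:
        raise ValueError(f"reserved markers not among candidates: {missing}")
    if len(by_id) < spec.target_size:
        raise ValueError(
            f"insufficient candidates: need {spec.target_size}, "
            f"have {len(by_id)} (short by {spec.target_size - len(by_id)})"
        )
    reserved = list(spec.reserved)
    rest = [c for c in by_id.values() if c.locus not in set(reserved)]
    rest.sort(key=lambda c: (-c.maf, -c.He, c.locus))
    return reserved + [c.locus for c in rest[: spec.target_size - len(reserved)]]
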