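"""Seeded generators for every input the pipeline consumes, with ground truth.

Three generators emulate the statistical structure the downstream analyses
assume:

* :func:`make_genome` - a synthetic draft assembly with recognition sites
  planted at exponential (Poisson-process) spacings, so that the realized
  fragment-length distribution is exactly the exponential model behind the
  design calculator.  Accidental occurrences of the site in the random
  background are scrubbed, making the planted positions the complete truth.
* :func:`make_pedigree_panel` - a diploid genotyping panel over a pedigree:
  founders drawn under Hardy-Weinberg proportions at configured minor allele
  frequencies, offspring by Mendelian transmission; X loci hemizygous in
  males (maternal X only), mitochondrial haplotypes maternal, Y markers
  present in males only.
* :func:`make_stack_fixtures` - consensus-stack records and alignment hits
  in labelled strata, each constructed to fail exactly one filter criterion
  (or none), so the filter cascade's output can be checked against planted
  truth.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stack_filter as sf
from .panel_stats import GenotypeMatrix
from .rrl_design import BGLII, RecognitionSite
from .stack_filter import AlignmentHit, StackRecord

__all__ = [
    "SimConfig",
    "TruthSet",
    "make_genome",
    "make_pedigree_panel",
    "make_stack_fixtures",
    "simulate_dyad_codes",
    "simulate_ld_pair",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the synthetic generators; defaults mirror the study design.

    The genome defaults give a 1 Mbp single-scaffold assembly with BglII
    sites at mean spacing 3100 bp (the mammalian-genome figure the design
    calculation assumes).  The panel defaults emulate a small validation
    panel: 87 autosomal SNPs, 3 X-linked SNPs, 4 mitochondrial markers and
    2 monomorphic Y markers, with founder minor allele frequencies drawn
    uniformly on [0.2, 0.5].
    """

    seed: int = 1
    # genome
    genome_length: int = 1_000_000
    n_scaffolds: int = 1
    site_density: float = 1.0 / 3100  # expected sites per bp
    site: RecognitionSite = BGLII
    # pedigree panel
    n_families: int = 2
    offspring_per_family: int = 1
    n_unrelated: int = 8
    n_autosomal: int = 87
    n_x: int = 3
    n_mt: int = 4
    n_y: int = 2
    maf_low: float = 0.2
    maf_high: float = 0.5
    # stack fixtures
    n_pass: int = 40
    n_per_failure: int = 10
    n_genotyped: int = 6
    read_len: int = 100

    def __post_init__(self) -> None:
        if self.site_density < 0 or not 0 <= self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("rates out of range")


@dataclass
class TruthSet:
    """Ground truth attached to generated data."""

    # genome
    sites: dict[str, list[int]] = field(default_factory=dict)
    # panel
    parents: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)
    sexes: dict[str, str] = field(default_factory=dict)
    locus_class: dict[str, str] = field(default_factory=dict)
    true_maf: dict[str, float] = field(default_factory=dict)
    po_dyads: list[tuple[str, str]] = field(default_factory=list)
    fullsib_dyads: list[tuple[str, str]] = field(default_factory=list)
    # stacks
    stack_outcomes: dict[str, str] = field(default_factory=dict)

    def relationship(self, a: str, b: str) -> str:
        """Pedigree relationship class of a dyad: PO, FS, HS or UN."""
        pa, pb = set(self.parents.get(a, ())), set(self.parents.get(b, ()))
        pa.discard(None)
        pb.discard(None)
        if a in pb or b in pa:
            return "PO"
        shared = pa & pb
        if len(shared) == 2:
            return "FS"
        if len(shared) == 1:
            return "HS"
        return "UN"


# ---------------------------------------------------------------------------
# genome


def _scrub_background(
    arr: np.ndarray, pattern: str, planted: set[int], rng: np.random.Generator
) -> None:
    """Re-randomise background bases until only planted site occurrences remain."""
    pat = np.frombuffer(pattern.encode(), dtype="S1")
    k = len(pat)
    protected = np.zeros(arr.size, dtype=bool)
    for p in planted:
        protected[p : p + k] = True
    for _ in range(200):
        s = arr.tobytes().decode()
        hits = []
        start = s.find(pattern)
        while start != -1:
            if start not in planted:
                hits.append(start)
            start = s.find(pattern, start + 1)
        if not hits:
            return
        for h in hits:
            span = np.arange(h, min(h + k, arr.size))
            span = span[~protected[span]]
            arr[span] = rng.choice(_BASES, size=span.size)
    raise RuntimeError("could not scrub accidental recognition sites")


def make_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], TruthSet]:
    """Random genome with recognition sites at exponential spacings.

    Returns ``({scaffold_id: sequence}, truth)`` where the truth records the
    planted site start positions per scaffold.  Background bases are i.i.d.
    uniform ACGT with any accidental pattern occurrence regenerated, so a
    scan finds exactly the planted sites.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    k = len(cfg.site.pattern)
    if cfg.site_density > 0 and 1.0 / cfg.site_density < 2 * k:
        raise ValueError("site density too high: sites would overlap")
    per_scaffold = cfg.genome_length // cfg.n_scaffolds
    seqs: dict[str, str] = {}
    truth = TruthSet()
    for s in range(cfg.n_scaffolds):
        name = f"scaffold_{s + 1}"
        arr = rng.choice(_BASES, size=per_scaffold)
        positions: list[int] = []
        if cfg.site_density > 0:
            pos = 0.0
            while True:
                # exponential gap; reject gaps that would overlap the last site
                gap = rng.exponential(1.0 / cfg.site_density)
                if gap < k:
                    continue
                pos += gap
                if pos + k > per_scaffold:
                    break
                positions.append(int(pos))
            pat = np.frombuffer(cfg.site.pattern.encode(), dtype="S1")
            for p in positions:
                arr[p : p + k] = pat
        _scrub_background(arr, cfg.site.pattern, set(positions), rng)
        seqs[name] = arr.tobytes().decode()
        truth.sites[name] = positions
    return seqs, truth


# ---------------------------------------------------------------------------
# pedigree panel


def _render_diploid(code: int) -> str:
    return {2: "AA", 1: "AB", 0: "BB"}[code]


def make_pedigree_panel(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, dict[str, float], TruthSet]:
    """Genotype a pedigree of families plus unrelated singletons.

    Each family is an unrelated founder couple with ``offspring_per_family``
    children of random sex.  Autosomal and X-linked founder genotypes are
    drawn under Hardy-Weinberg proportions from per-locus allele frequencies
    with MAF uniform on [maf_low, maf_high]; offspring receive one allele
    from each parent (sons their single X from the mother).  Mitochondrial
    haplotypes (one of the three recognized lineages) follow the maternal
    line; the two Y markers are present in males only.

    Returns the matrix, the true allele-A frequencies used for simulation,
    and a truth set with the pedigree and per-locus classes.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    truth = TruthSet()

    aut = [f"aut{i + 1:03d}" for i in range(cfg.n_autosomal)]
    x_loci = [f"x{i + 1}" for i in range(cfg.n_x)]
    mt_loci = [f"mt{i + 1}" for i in range(cfg.n_mt)]
    y_loci = [f"y{i + 1}" for i in range(cfg.n_y)]
    for l in aut:
        truth.locus_class[l] = "autosomal"
    for l in x_loci:
        truth.locus_class[l] = "X"
    for l in mt_loci:
        truth.locus_class[l] = "mtDNA"
    for l in y_loci:
        truth.locus_class[l] = "Y"

    def draw_p(n: int) -> np.ndarray:
        maf = rng.uniform(cfg.maf_low, cfg.maf_high, size=n)
        # the minor allele is A or B with equal chance
        return np.where(rng.random(n) < 0.5, maf, 1 - maf)

    p_aut = draw_p(cfg.n_autosomal)
    p_x = draw_p(cfg.n_x)
    for l, p in zip(aut, p_aut):
        truth.true_maf[l] = float(min(p, 1 - p))
    for l, p in zip(x_loci, p_x):
        truth.true_maf[l] = float(min(p, 1 - p))

    # three recognized maternal lineages at the four mtDNA markers
    mt_haps = ["ABAA", "AAAA", "BBBB"]

    individuals: list[str] = []
    rows: dict[str, dict[str, str]] = {}
    aut_codes: dict[str, np.ndarray] = {}
    x_codes: dict[str, np.ndarray] = {}  # females 0..2, males 0..1
    mt_of: dict[str, str] = {}

    def add(ind: str, sex: str, parents: tuple[str | None, str | None]) -> None:
        individuals.append(ind)
        truth.sexes[ind] = sex
        truth.parents[ind] = parents

    def founder(ind: str, sex: str) -> None:
        add(ind, sex, (None, None))
        aut_codes[ind] = rng.binomial(2, p_aut)
        x_codes[ind] = rng.binomial(2 if sex == "F" else 1, p_x)
        mt_of[ind] = mt_haps[rng.integers(len(mt_haps))]

    def transmit(parent_codes: np.ndarray, ploidy: int) -> np.ndarray:
        return rng.binomial(1, parent_codes / ploidy)

    def child(ind: str, sex: str, mother: str, father: str) -> None:
        add(ind, sex, (mother, father))
        aut_codes[ind] = transmit(aut_codes[mother], 2) + transmit(
            aut_codes[father], 2
        )
        maternal_x = transmit(x_codes[mother], 2)
        if sex == "M":
            x_codes[ind] = maternal_x
        else:
            x_codes[ind] = maternal_x + x_codes[father]  # father hemizygous
        mt_of[ind] = mt_of[mother]

    for f in range(cfg.n_families):
        mo, fa = f"F{f + 1}_mo", f"F{f + 1}_fa"
        founder(mo, "F")
        founder(fa, "M")
        kids = []
        for c in range(cfg.offspring_per_family):
            kid = f"F{f + 1}_c{c + 1}"
            child(kid, "M" if rng.random() < 0.5 else "F", mo, fa)
            truth.po_dyads.extend([(mo, kid), (fa, kid)])
            kids.append(kid)
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                truth.fullsib_dyads.append((kids[i], kids[j]))
    for u in range(cfg.n_unrelated):
        founder(f"U{u + 1}", "M" if u % 2 else "F")

    for ind in individuals:
        sex = truth.sexes[ind]
        row: dict[str, str] = {}
        for l, code in zip(aut, aut_codes[ind]):
            row[l] = _render_diploid(int(code))
        for l, code in zip(x_loci, x_codes[ind]):
            if sex == "M":
                row[l] = "A" if code == 1 else "B"
            else:
                row[l] = _render_diploid(int(code))
        for l, allele in zip(mt_loci, mt_of[ind]):
            row[l] = allele
        for l in y_loci:
            row[l] = "A" if sex == "M" else "--"
        rows[ind] = row

    calls = pd.DataFrame.from_dict(rows, orient="index")
    calls = calls.loc[individuals, aut + x_loci + mt_loci + y_loci]
    matrix = GenotypeMatrix(calls, truth.sexes, truth.locus_class)
    freqs = {l: float(p) for l, p in zip(aut, p_aut)}
    freqs.update({l: float(p) for l, p in zip(x_loci, p_x)})
    return matrix, freqs, truth


def simulate_dyad_codes(
    relationship: str,
    n_dyads: int,
    n_loci: int,
    rng: np.random.Generator,
    maf_low: float = 0.2,
    maf_high: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized dyad simulator for parameter-recovery experiments.

    Returns ``(gx, gy, p)`` where ``gx``/``gy`` are (n_dyads, n_loci)
    A-allele counts for the two members of each dyad and ``p`` the shared
    per-locus allele-A frequencies.  Relationships: ``po`` (parent and
    offspring), ``fullsib``, ``halfsib``, ``unrelated``, ``self``.
    """
    maf = rng.uniform(maf_low, maf_high, size=n_loci)
    p = np.where(rng.random(n_loci) < 0.5, maf, 1 - maf)
    shape = (n_dyads, n_loci)

    def founders() -> np.ndarray:
        return rng.binomial(2, np.broadcast_to(p, shape))

    def gamete(g: np.ndarray) -> np.ndarray:
        return rng.binomial(1, g / 2)

    if relationship == "unrelated":
        return founders(), founders(), p
    if relationship == "self":
        g = founders()
        return g, g.copy(), p
    if relationship == "po":
        parent = founders()
        other = founders()
        child = gamete(parent) + gamete(other)
        return parent, child, p
    if relationship == "fullsib":
        m, f = founders(), founders()
        s1 = gamete(m) + gamete(f)
        s2 = gamete(m) + gamete(f)
        return s1, s2, p
    if relationship == "halfsib":
        shared, o1, o2 = founders(), founders(), founders()
        s1 = gamete(shared) + gamete(o1)
        s2 = gamete(shared) + gamete(o2)
        return s1, s2, p
    raise ValueError(f"unknown relationship {relationship!r}")


def simulate_ld_pair(
    n: int,
    p_a: float,
    p_b: float,
    dprime: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Unphased genotypes at two loci with a planted D' value.

    Haplotype frequencies are constructed from the target D' (positive D),
    two haplotypes drawn per individual, then collapsed to diploid codes.
    """
    if not 0 <= dprime <= 1:
        raise ValueError("dprime must lie in [0, 1]")
    dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    D = dprime * dmax
    h = np.array(
        [
            p_a * p_b + D,
            p_a * (1 - p_b) - D,
            (1 - p_a) * p_b - D,
            (1 - p_a) * (1 - p_b) + D,
        ]
    )
    if (h < -1e-12).any():
        raise ValueError("infeasible haplotype frequencies")
    h = np.clip(h, 0, None)
    h /= h.sum()
    draws = rng.choice(4, size=(n, 2), p=h)
    a_allele = (draws <= 1).astype(int)  # haplotypes 0,1 carry A at locus 1
    b_allele = ((draws == 0) | (draws == 2)).astype(int)
    return a_allele.sum(axis=1), b_allele.sum(axis=1)


# ---------------------------------------------------------------------------
# stack fixtures


def _random_consensus(
    n: int, rng: np.random.Generator, max_run: int = 3
) -> str:
    """Random sequence whose longest single-base run is <= max_run."""
    out = []
    run = 0
    prev = ""
    for _ in range(n):
        choices = [b for b in "ACGT" if not (b == prev and run >= max_run)]
        base = choices[rng.integers(len(choices))]
        run = run + 1 if base == prev else 1
        prev = base
        out.append(base)
    return "".join(out)


def _alt_of(ref: str, rng: np.random.Generator) -> str:
    others = [b for b in "ACGT" if b != ref]
    return others[rng.integers(3)]


_PASS_CALL_CYCLE = ("aa", "ab", "bb")


def _full_calls(n_ind: int) -> list[str]:
    return [_PASS_CALL_CYCLE[i % 3] for i in range(n_ind)]


def make_stack_fixtures(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[StackRecord], list[AlignmentHit], TruthSet]:
    """Stack records and alignment hits in labelled single-failure strata.

    ``cfg.n_pass`` clean records pass every criterion; each failure stratum
    (``cfg.n_per_failure`` records, the scaffold-sharing stratum rounded up
    to pairs) violates exactly one criterion.  The truth set maps each stack
    id to ``"pass"`` or the rejection reason the cascade should report.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    truth = TruthSet()
    records: list[StackRecord] = []
    hits: list[AlignmentHit] = []
    L = cfg.read_len
    n_ind = cfg.n_genotyped
    inds = [f"ind{i + 1}" for i in range(n_ind)]
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"stack{counter:04d}"

    def snp_at(pos: int, consensus: str) -> tuple[int, str, str]:
        return (pos, consensus[pos], _alt_of(consensus[pos], rng))

    def mid_pos() -> int:
        return int(rng.integers(20, 65))

    def genotypes(calls: Sequence[str], n_snps: int = 1) -> dict:
        return {ind: (c,) * n_snps for ind, c in zip(inds, calls)}

    def clean_hit(sid: str, scaffold: str | None = None) -> AlignmentHit:
        return AlignmentHit(
            stack_id=sid,
            scaffold_id=scaffold or f"scaf_{sid}",
            identity_pct=100.0,
            align_len=L,
            mismatches=0,
            gap_opens=0,
        )

    # clean passes
    for _ in range(cfg.n_pass):
        sid = new_id()
        cons = _random_consensus(L, rng)
        rec = StackRecord(sid, cons, (snp_at(mid_pos(), cons),), genotypes(_full_calls(n_ind)))
        records.append(rec)
        hits.append(clean_hit(sid))
        truth.stack_outcomes[sid] = "pass"

    def failure(reason: str, build) -> None:
        for k in range(cfg.n_per_failure):
            sid = new_id()
            build(sid, k)
            truth.stack_outcomes[sid] = reason

    def f_multi_snp(sid, k):
        cons = _random_consensus(L, rng)
        p1 = int(rng.integers(20, 40))
        p2 = int(rng.integers(45, 65))
        rec = StackRecord(
            sid, cons, (snp_at(p1, cons), snp_at(p2, cons)),
            genotypes(_full_calls(n_ind), n_snps=2),
        )
        records.append(rec)
        hits.append(clean_hit(sid))

    def f_position(sid, k):
        cons = _random_consensus(L, rng)
        pos = int(rng.integers(0, 20)) if k % 2 else int(rng.integers(65, L))
        rec = StackRecord(sid, cons, (snp_at(pos, cons),), genotypes(_full_calls(n_ind)))
        records.append(rec)
        hits.append(clean_hit(sid))

    def f_classes(sid, k):
        cons = _random_consensus(L, rng)
        if k % 2:  # fewer than three called individuals
            calls = ["aa", "bb"] + ["--"] * (n_ind - 2)
        else:  # missing the bb class
            calls = ["aa", "ab"] * (n_ind // 2) + ["aa"] * (n_ind % 2)
        rec = StackRecord(sid, cons, (snp_at(mid_pos(), cons),), genotypes(calls))
        records.append(rec)
        hits.append(clean_hit(sid))

    def f_low_identity(sid, k):
        cons = _random_consensus(L, rng)
        rec = StackRecord(sid, cons, (snp_at(mid_pos(), cons),), genotypes(_full_calls(n_ind)))
        records.append(rec)
        hits.append(
            AlignmentHit(sid, f"scaf_{sid}", 96.0 + rng.random() * 2.5, L, 3, 0)
        )

    def f_gapped(sid, k):
        cons = _random_consensus(L, rng)
        rec = StackRecord(sid, cons, (snp_at(mid_pos(), cons),), genotypes(_full_calls(n_ind)))
        records.append(rec)
        hits.append(AlignmentHit(sid, f"scaf_{sid}", 99.5, L, 0, 1))

    def f_multimapped(sid, k):
        cons = _random_consensus(L, rng)
        rec = StackRecord(sid, cons, (snp_at(mid_pos(), cons),), genotypes(_full_calls(n_ind)))
        records.append(rec)
        hits.append(clean_hit(sid, f"scafA_{sid}"))
        hits.append(clean_hit(sid, f"scafB_{sid}"))

    def f_unaligned(sid, k):
        cons = _random_consensus(L, rng)
        rec = StackRecord(sid, cons, (snp_at(mid_pos(), cons),), genotypes(_full_calls(n_ind)))
        records.append(rec)

    shared_pair_state: dict[str, str] = {}

    def f_shared_scaffold(sid, k):
        cons = _random_consensus(L, rng)
        rec = StackRecord(sid, cons, (snp_at(mid_pos(), cons),), genotypes(_full_calls(n_ind)))
        records.append(rec)
        hits.append(clean_hit(sid, f"shared_scaf_{k // 2 + 1}"))

    def f_homopolymer(sid, k):
        cons = list(_random_consensus(L, rng))
        pos = 42
        run_base = "ACGT"[k % 4]
        start = pos - 10 if k % 2 else pos + 4
        cons[start : start + 6] = run_base * 6
        # keep the SNP base distinct from a run directly abutting it
        cons_str = "".join(cons)
        rec = StackRecord(
            sid, cons_str, (snp_at(pos, cons_str),), genotypes(_full_calls(n_ind))
        )
        records.append(rec)
        hits.append(clean_hit(sid))

    failure(sf.STEP_SINGLE, f_multi_snp)
    failure(sf.STEP_POSITION, f_position)
    failure(sf.STEP_CLASSES, f_classes)
    failure(sf.REASON_LOW_IDENTITY, f_low_identity)
    failure(sf.REASON_GAPPED, f_gapped)
    failure(sf.REASON_MULTIMAPPED, f_multimapped)
    failure(sf.REASON_UNALIGNED, f_unaligned)
    n_shared = cfg.n_per_failure + (cfg.n_per_failure % 2)  # need pairs
    for k in range(n_shared):
        sid = new_id()
        f_shared_scaffold(sid, k)
        truth.stack_outcomes[sid] = sf.STEP_SCAFFOLD
    failure(sf.STEP_HOMOPOLYMER, f_homopolymer)

    return records, hits, truth
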