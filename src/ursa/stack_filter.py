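"""SNP filter cascade for consensus-stack records.

Putative SNPs discovered on 100-nt consensus reads ("stacks" assembled from
co-aligning restriction-fragment reads) are winnowed through a sequence of
criteria designed to retain only assayable, high-confidence, unlinked sites:

1. ``single_snp``       - exactly one SNP on the read (multi-SNP reads are
                          likely hypervariable or error-ridden);
2. ``snp_position``     - the SNP sits centrally, leaving >= 20 nt of 5'
                          flank and >= 35 nt of 3' flank for assay design;
3. ``min_individuals_and_classes`` - called in >= 3 individuals with all
                          three genotype classes (aa, ab, bb) observed;
4. ``unique_alignment`` - exactly one high-identity (>= 99%), gap-free hit
                          against the draft assembly (paralog screen);
5. ``scaffold_unique``  - no second surviving SNP on the same scaffold
                          (physical-linkage screen);
6. ``homopolymer``      - no long single-nucleotide run in the flanking
                          sequence near the SNP.

The first three criteria use only the stack records and are order
independent; the alignment-based criteria consume externally produced
blast-tabular hits.  SNP positions are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "StackRecord",
    "AlignmentHit",
    "FilterConfig",
    "FilterReport",
    "fc_single_snp",
    "fc_position",
    "fc_individuals_and_classes",
    "fc_alignment",
    "fc_scaffold_unique",
    "fc_homopolymer",
    "run_pipeline",
    "find_variable_sites",
]

GENOTYPE_CALLS = frozenset({"aa", "ab", "bb", "--"})
MISSING = "--"

# canonical criterion / rejection-reason names, in cascade order
STEP_SINGLE = "single_snp"
STEP_POSITION = "snp_position"
STEP_CLASSES = "min_individuals_and_classes"
STEP_ALIGNMENT = "unique_alignment"
STEP_SCAFFOLD = "scaffold_unique"
STEP_HOMOPOLYMER = "homopolymer"

REASON_UNALIGNED = "unaligned"
REASON_LOW_IDENTITY = "low_identity"
REASON_GAPPED = "gapped_alignment"
REASON_MULTIMAPPED = "multiple_alignments"


@dataclass(frozen=True)
class StackRecord:
    """One consensus stack: sequence, its SNP(s) and per-individual calls.

    ``snps`` is a list of ``(position, ref_allele, alt_allele)`` with 0-based
    positions on ``consensus``.  ``genotypes`` maps individual id to one call
    per SNP, each in ``{aa, ab, bb, --}`` ("--" = missing).
    """

    stack_id: str
    consensus: str
    snps: tuple[tuple[int, str, str], ...]
    genotypes: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "snps", tuple(tuple(s) for s in self.snps))
        object.__setattr__(
            self, "genotypes", {k: tuple(v) for k, v in self.genotypes.items()}
        )
        for pos, ref, alt in self.snps:
            if not 0 <= pos < len(self.consensus):
                raise ValueError(
                    f"{self.stack_id}: SNP position {pos} outside consensus"
                )
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                raise ValueError(
                    f"{self.stack_id}: alleles must be distinct single bases"
                )
        for ind, calls in self.genotypes.items():
            if len(calls) != len(self.snps):
                raise ValueError(
                    f"{self.stack_id}/{ind}: {len(calls)} calls for "
                    f"{len(self.snps)} SNPs"
                )
            bad = set(calls) - GENOTYPE_CALLS
            if bad:
                raise ValueError(f"{self.stack_id}/{ind}: bad calls {bad}")


@dataclass(frozen=True)
class AlignmentHit:
    """A blast-tabular-style alignment of a stack against the assembly."""

    stack_id: str
    scaffold_id: str
    identity_pct: float
    align_len: int
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.identity_pct <= 100:
            raise ValueError(f"identity {self.identity_pct} outside 0..100")


@dataclass(frozen=True)
class FilterConfig:
    min_flank5: int = 20
    min_flank3: int = 35
    min_individuals: int = 3
    min_identity_pct: float = 99.0
    allow_gaps: bool = False
    require_unique_hit: bool = True
    max_homopolymer_run: int = 5
    flank_scan_len: int = 20

    def __post_init__(self) -> None:
        nonneg = (
            self.min_flank5,
            self.min_flank3,
            self.min_individuals,
            self.min_identity_pct,
            self.max_homopolymer_run,
            self.flank_scan_len,
        )
        if any(v < 0 for v in nonneg):
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class FilterReport:
    """Per-criterion surviving counts plus survivor/rejection bookkeeping."""

    steps: list[tuple[str, int]] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)
    scaffold_of: dict[str, str] = field(default_factory=dict)
    rejections: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "steps": [{"criterion": name, "surviving": n} for name, n in self.steps],
            "survivors": list(self.survivors),
            "scaffold_of": dict(sorted(self.scaffold_of.items())),
            "rejections": dict(sorted(self.rejections.items())),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _require_single(record: StackRecord) -> tuple[int, str, str]:
    if len(record.snps) != 1:
        raise ValueError(f"{record.stack_id}: expected exactly one SNP")
    return record.snps[0]


def fc_single_snp(record: StackRecord) -> bool:
    """Pass iff the record carries exactly one SNP."""
    return len(record.snps) == 1


def fc_position(record: StackRecord, cfg: FilterConfig = FilterConfig()) -> bool:
    """Pass iff the SNP leaves at least ``min_flank5``/``min_flank3`` bases
    strictly 5'/3' of it (0-based positions 20..64 on a 100-nt read)."""
    pos, _, _ = _require_single(record)
    n = len(record.consensus)
    return pos >= cfg.min_flank5 and (n - 1 - pos) >= cfg.min_flank3


def fc_individuals_and_classes(
    record: StackRecord, cfg: FilterConfig = FilterConfig()
) -> bool:
    """Pass iff >= ``min_individuals`` non-missing calls and all of
    aa/ab/bb observed at least once."""
    _require_single(record)
    calls = [c[0] for c in record.genotypes.values() if c[0] != MISSING]
    return len(calls) >= cfg.min_individuals and {"aa", "ab", "bb"} <= set(calls)


def fc_alignment(
    hits: Sequence[AlignmentHit], cfg: FilterConfig = FilterConfig()
) -> tuple[bool, str | None, str | None]:
    """Evaluate the paralog screen for one stack's hits.

    A qualifying hit has identity >= ``min_identity_pct`` and (unless
    ``allow_gaps``) no gap opens.  Returns ``(passed, scaffold_id, reason)``:
    the stack passes iff exactly one qualifying hit exists.
    """
    qualifying = [
        h
        for h in hits
        if h.identity_pct >= cfg.min_identity_pct
        and (cfg.allow_gaps or h.gap_opens == 0)
    ]
    if len(qualifying) == 1:
        return True, qualifying[0].scaffold_id, None
    if not hits:
        return False, None, REASON_UNALIGNED
    if len(qualifying) > 1:
        return False, None, REASON_MULTIMAPPED
    if any(h.identity_pct >= cfg.min_identity_pct and h.gap_opens > 0 for h in hits):
        return False, None, REASON_GAPPED
    return False, None, REASON_LOW_IDENTITY


def fc_scaffold_unique(snp_to_scaffold: Mapping[str, str]) -> set[str]:
    """Drop every SNP on a scaffold that carries two or more surviving SNPs."""
    counts: dict[str, int] = {}
    for scaffold in snp_to_scaffold.values():
        counts[scaffold] = counts.get(scaffold, 0) + 1
    return {s for s, scaf in snp_to_scaffold.items() if counts[scaf] == 1}


def _max_run(s: str) -> int:
    best = run = 0
    prev = ""
    for ch in s:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def fc_homopolymer(record: StackRecord, cfg: FilterConfig = FilterConfig()) -> bool:
    """Fail iff either flank, scanned ``flank_scan_len`` nt outward from the
    SNP, contains a single-nucleotide run longer than ``max_homopolymer_run``."""
    pos, _, _ = _require_single(record)
    seq = record.consensus.upper()
    left = seq[max(0, pos - cfg.flank_scan_len) : pos]
    right = seq[pos + 1 : pos + 1 + cfg.flank_scan_len]
    return max(_max_run(left), _max_run(right)) <= cfg.max_homopolymer_run


def run_pipeline(
    records: Sequence[StackRecord],
    hits: Iterable[AlignmentHit],
    cfg: FilterConfig = FilterConfig(),
) -> FilterReport:
    """Apply the full cascade and report per-criterion surviving counts.

    Criteria run in the documented order; each rejected stack is annotated
    with the name of the criterion (or the specific alignment reason) that
    removed it.  Alignment hits naming unknown stacks are an input error.
    """
    by_id = {r.stack_id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate stack ids in input")
    hits_by_stack: dict[str, list[AlignmentHit]] = {r.stack_id: [] for r in records}
    orphans = []
    for h in hits:
        if h.stack_id not in hits_by_stack:
            orphans.append(h.stack_id)
        else:
            hits_by_stack[h.stack_id].append(h)
    if orphans:
        raise ValueError(
            f"alignment hits reference unknown stacks: {sorted(set(orphans))}"
        )

    report = FilterReport()
    alive = [r.stack_id for r in records]
    report.steps.append(("input", len(alive)))

    def apply(name: str, keep_fn) -> None:
        nonlocal alive
        kept = []
        for sid in alive:
            ok, reason = keep_fn(sid)
            if ok:
                kept.append(sid)
            else:
                report.rejections[sid] = reason or name
        alive = kept
        report.steps.append((name, len(alive)))

    apply(STEP_SINGLE, lambda sid: (fc_single_snp(by_id[sid]), None))
    apply(STEP_POSITION, lambda sid: (fc_position(by_id[sid], cfg), None))
    apply(
        STEP_CLASSES,
        lambda sid: (fc_individuals_and_classes(by_id[sid], cfg), None),
    )

    def align_step(sid: str):
        ok, scaffold, reason = fc_alignment(hits_by_stack[sid], cfg)
        if ok:
            report.scaffold_of[sid] = scaffold
        return ok, reason

    apply(STEP_ALIGNMENT, align_step)

    unique = fc_scaffold_unique({sid: report.scaffold_of[sid] for sid in alive})
    apply(STEP_SCAFFOLD, lambda sid: (sid in unique, None))
    apply(STEP_HOMOPOLYMER, lambda sid: (fc_homopolymer(by_id[sid], cfg), None))

    report.survivors = list(alive)
    report.scaffold_of = {sid: report.scaffold_of[sid] for sid in alive}
    return report


def find_variable_sites(
    aligned_seqs: Sequence[str],
) -> list[tuple[int, tuple[str, ...]]]:
    """Variable columns of a set of pre-aligned, equal-length sequences.

    Used for Sanger-based SNP discovery (e.g. mitochondrial amplicons):
    returns ``(position, alleles)`` for every column with two or more
    distinct non-gap, non-N characters.
    """
    if len(aligned_seqs) < 2:
        raise ValueError("need at least two sequences")
    seqs = [s.upper() for s in aligned_seqs]
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    out = []
    for i in range(n):
        alleles = sorted({s[i] for s in seqs} - {"-", "N"})
        if len(alleles) >= 2:
            out.append((i, tuple(alleles)))
    return out
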