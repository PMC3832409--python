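"""Reduced-representation library (RRL) design via in-silico restriction digestion.

A reduced representation library samples a size-selected subset of restriction
fragments so that the same genomic loci are sequenced in every individual.
Before sequencing, the number of fragments falling in the size-selection
window can be predicted from the genome size ``G`` and the mean fragment
length ``d`` of the enzyme, modelling fragment lengths as exponential with
mean ``d``: the expected count in ``[a, b]`` is ``(G/d) (e^{-a/d} - e^{-b/d})``.
Once a draft assembly is available, the same quantities are measured directly
by digesting the assembly in silico and comparing against the predictions.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RecognitionSite",
    "BGLII",
    "Fragment",
    "DigestResult",
    "DesignParams",
    "DesignSummary",
    "digest_sequence",
    "digest_genome",
    "size_select",
    "expected_fragment_count",
    "design_summary",
    "percent_diff",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class RecognitionSite:
    """A restriction-enzyme recognition sequence and its cut position.

    ``cut_offset`` is the position of the cut within the pattern, 5'->3'
    (e.g. BglII A^GATCT has pattern ``AGATCT`` and offset 1).
    """

    pattern: str
    cut_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        if not self.pattern or set(self.pattern) - _ACGT:
            raise ValueError(
                f"recognition pattern must be non-empty A/C/G/T, got {self.pattern!r}"
            )
        if not 0 <= self.cut_offset <= len(self.pattern):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside 0..{len(self.pattern)}"
            )


#: BglII, the enzyme used throughout: A^GATCT.
BGLII = RecognitionSite("AGATCT", 1)


@dataclass(frozen=True)
class Fragment:
    """A digest fragment, 0-based half-open on its scaffold."""

    scaffold_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty fragment {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DigestResult:
    fragments: tuple[Fragment, ...]
    genome_size: int

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def mean_length(self) -> float:
        return self.genome_size / len(self.fragments)


@dataclass(frozen=True)
class DesignParams:
    """Inputs to the RRL design calculation."""

    d: float  # mean fragment length (bp)
    G: float  # genome size (bp)
    a: float = 100.0  # size-selection lower bound (bp)
    b: float = 700.0  # size-selection upper bound (bp)
    read_len: int = 100
    yield_per_individual: float = 1.0e9  # sequenced bp per individual
    n_individuals: int = 10

    def __post_init__(self) -> None:
        if min(self.d, self.G, self.read_len, self.yield_per_individual) <= 0:
            raise ValueError("design parameters must be positive")
        if not self.a < self.b:
            raise ValueError("size window requires a < b")


@dataclass(frozen=True)
class DesignSummary:
    D: int  # size-selected fragment count
    depth: int  # X-fold per individual, rounded
    coverage_pct: float  # percent of genome, 2 decimals


def digest_sequence(
    seq: str, site: RecognitionSite, scaffold_id: str = "seq"
) -> list[Fragment]:
    """Cut ``seq`` at every exact occurrence of the recognition pattern.

    The cut falls at ``occurrence_start + cut_offset``.  Terminal fragments
    are included, so fragment lengths always sum to ``len(seq)``.  Pattern
    matching is exact and case-insensitive; windows containing ambiguity
    characters (e.g. N) never match.
    """
    if not isinstance(site, RecognitionSite):
        raise TypeError("site must be a RecognitionSite")
    if not seq:
        return []
    s = seq.upper()
    # lookahead so overlapping occurrences are all found
    pat = re.compile(f"(?={re.escape(site.pattern)})")
    cuts = sorted(
        {
            m.start() + site.cut_offset
            for m in pat.finditer(s)
            if 0 < m.start() + site.cut_offset < len(s)
        }
    )
    bounds = [0, *cuts, len(s)]
    return [
        Fragment(scaffold_id, lo, hi) for lo, hi in zip(bounds, bounds[1:])
    ]


def digest_genome(
    seqs: Mapping[str, str], site: RecognitionSite = BGLII
) -> DigestResult:
    """Digest every scaffold of a genome; report totals over all fragments."""
    if not seqs:
        raise ValueError("genome has no sequences")
    fragments: list[Fragment] = []
    total = 0
    for scaffold_id, seq in seqs.items():
        fragments.extend(digest_sequence(seq, site, scaffold_id))
        total += len(seq)
    return DigestResult(tuple(fragments), total)


def size_select(
    fragments: Iterable[Fragment], a: float, b: float, inclusive: bool = True
) -> list[Fragment]:
    """Keep fragments whose length lies in the selection window.

    Bounds are inclusive by default (``a <= length <= b``), the reading taken
    of a 100-700 bp gel excision; exclusive bounds are available via
    ``inclusive=False``.  Input order is preserved.
    """
    if not a < b:
        raise ValueError("size window requires a < b")
    if inclusive:
        return [f for f in fragments if a <= f.length <= b]
    return [f for f in fragments if a < f.length < b]


def expected_fragment_count(d: float, G: float, a: float, b: float) -> float:
    """Expected number of fragments with length in ``[a, b]``.

    Under random cutting, fragment lengths are exponential with mean ``d``;
    with ``G/d`` fragments in total the expected count in the window is
    ``(G/d) (e^{-a/d} - e^{-b/d})``.
    """
    if d <= 0 or G <= 0:
        raise ValueError("d and G must be positive")
    if a > b:
        raise ValueError("window requires a <= b")
    return (G / d) * (math.exp(-a / d) - math.exp(-b / d))


def design_summary(
    D: int, G: float, read_len: int = 100, yield_per_individual: float = 1.0e9
) -> DesignSummary:
    """Coverage and per-individual depth of a paired-end RRL design.

    With ``D`` size-selected fragments sequenced as 2 x ``read_len`` bp
    paired-end reads, the maximum genomic coverage is
    ``D * 2 * read_len / G`` and the per-individual depth is
    ``yield_per_individual / (D * 2 * read_len)``.  Coverage is reported as a
    percentage rounded to two decimals, depth to the nearest integer.
    """
    if D <= 0:
        raise ValueError("degenerate design: no size-selected fragments (D = 0)")
    if G <= 0 or read_len <= 0 or yield_per_individual <= 0:
        raise ValueError("G, read_len and yield must be positive")
    targeted = D * 2 * read_len
    coverage_pct = round(targeted / G * 100, 2)
    depth = round(yield_per_individual / targeted)
    return DesignSummary(D=D, depth=int(depth), coverage_pct=coverage_pct)


def percent_diff(estimated: float, actual: float) -> float:
    """Signed percent difference, relative to the estimate.

    ``(estimated - actual) / estimated * 100`` to one decimal; negative values
    mean the estimate undershot the realized quantity.
    """
    if estimated == 0:
        raise ValueError("estimated value must be nonzero")
    return round((estimated - actual) / estimated * 100, 1)
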