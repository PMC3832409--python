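"""Readers and writers for the pipeline's plain-text interchange formats.

All tabular formats are TSV (matching the blast-tabular convention), UTF-8,
Unix newlines.  Serialized coordinates are 0-based half-open, stated in a
header comment of every coordinate-bearing file.  Missing genotype calls are
``--``.
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel_stats import GenotypeMatrix, LocusStats
from .relatedness import DyadReport
from .rrl_design import Fragment
from .stack_filter import AlignmentHit, FilterReport, StackRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fragments_bed",
    "read_catalog",
    "write_catalog",
    "read_alignment_hits",
    "read_genotypes",
    "write_genotypes",
    "write_locus_stats",
    "write_dyad_table",
    "write_report",
]

COORD_COMMENT = "# coordinates: 0-based, half-open"


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, encoding="utf-8")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-FASTA into ``{id: SEQUENCE}``.

    Sequences are case-folded to upper.  An empty file is an error.
    """
    with _open_text(path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_fragments_bed(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Fragments as BED3 plus a length column."""
    with _open_text(path, "wt") as fh:
        fh.write(COORD_COMMENT + "\n")
        fh.write("#chrom\tstart\tend\tlength\n")
        for f in fragments:
            fh.write(f"{f.scaffold_id}\t{f.start}\t{f.end}\t{f.length}\n")


# ---------------------------------------------------------------------------
# stack catalog


def write_catalog(
    records: Sequence[StackRecord], path: str | Path
) -> None:
    """Stacks-like catalog TSV.

    Columns: stack_id, consensus, snp_pos (comma list, 0-based), alleles
    (comma list of ref/alt), then one column per individual holding the
    comma-joined per-SNP calls (aa|ab|bb|--).
    """
    individuals = sorted({ind for r in records for ind in r.genotypes})
    with _open_text(path, "wt") as fh:
        fh.write(COORD_COMMENT + " (snp_pos on consensus)\n")
        fh.write("\t".join(["stack_id", "consensus", "snp_pos", "alleles"] + individuals) + "\n")
        for r in records:
            pos = ",".join(str(p) for p, _, _ in r.snps)
            alleles = ",".join(f"{ref}/{alt}" for _, ref, alt in r.snps)
            cells = [
                ",".join(r.genotypes[ind]) if ind in r.genotypes else ""
                for ind in individuals
            ]
            fh.write("\t".join([r.stack_id, r.consensus, pos, alleles] + cells) + "\n")


def read_catalog(path: str | Path) -> list[StackRecord]:
    with _open_text(path) as fh:
        lines = [l.rstrip("\n") for l in fh if not l.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty catalog")
    header = lines[0].split("\t")
    if header[:4] != ["stack_id", "consensus", "snp_pos", "alleles"]:
        raise ValueError(f"{path}: unexpected catalog header {header[:4]}")
    individuals = header[4:]
    records = []
    for ln, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        sid, consensus, pos_s, alleles_s = fields[:4]
        if pos_s:
            positions = [int(p) for p in pos_s.split(",")]
            pairs = [a.split("/") for a in alleles_s.split(",")]
            snps = tuple(
                (p, ref, alt) for p, (ref, alt) in zip(positions, pairs)
            )
        else:
            snps = ()
        genotypes = {}
        for ind, cell in zip(individuals, fields[4:]):
            if cell == "" and snps:
                continue
            genotypes[ind] = tuple(cell.split(",")) if cell else ()
        try:
            records.append(StackRecord(sid, consensus, snps, genotypes))
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: {e}") from e
    return records


# ---------------------------------------------------------------------------
# alignment hits


def read_alignment_hits(path: str | Path) -> list[AlignmentHit]:
    """Blast-tabular-like TSV: qseqid sseqid pident length mismatch gapopen.

    A header row naming the columns is optional; ``#`` comment lines are
    skipped; extra columns are ignored.
    """
    with _open_text(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        return []
    start = 0
    if lines[0].split("\t")[0] == "qseqid":
        start = 1
    hits = []
    for ln, line in enumerate(lines[start:], start=start + 1):
        f = line.split("\t")
        if len(f) < 6:
            raise ValueError(f"{path}:{ln}: expected >= 6 columns")
        try:
            hits.append(
                AlignmentHit(
                    stack_id=f[0],
                    scaffold_id=f[1],
                    identity_pct=float(f[2]),
                    align_len=int(f[3]),
                    mismatches=int(f[4]),
                    gap_opens=int(f[5]),
                )
            )
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: {e}") from e
    return hits


# ---------------------------------------------------------------------------
# genotype matrix


def write_genotypes(
    matrix: GenotypeMatrix, geno_path: str | Path, loci_path: str | Path
) -> None:
    """Genotypes TSV (id, sex, group, one column per locus) + locus metadata."""
    with _open_text(geno_path, "wt") as fh:
        loci = matrix.loci
        fh.write("\t".join(["id", "sex", "group"] + loci) + "\n")
        for ind in matrix.individuals:
            row = [ind, matrix.sex[ind], matrix.group.get(ind, "")]
            row += [matrix.calls.at[ind, l] for l in loci]
            fh.write("\t".join(row) + "\n")
    with _open_text(loci_path, "wt") as fh:
        fh.write("locus\tclass\n")
        for l in matrix.loci:
            fh.write(f"{l}\t{matrix.locus_class[l]}\n")


def read_genotypes(
    geno_path: str | Path, loci_path: str | Path
) -> GenotypeMatrix:
    loci_df = pd.read_csv(loci_path, sep="\t", dtype=str, comment="#")
    locus_class = dict(zip(loci_df["locus"], loci_df["class"]))
    df = pd.read_csv(geno_path, sep="\t", dtype=str, comment="#").fillna("")
    for col in ("id", "sex"):
        if col not in df.columns:
            raise ValueError(f"{geno_path}: missing required column {col!r}")
    df = df.set_index("id")
    sex = {}
    for ind, s in df["sex"].items():
        if s not in ("M", "F", "unknown"):
            warnings.warn(f"unknown sex token {s!r} for {ind}; parsed as unknown")
            s = "unknown"
        sex[ind] = s
    group = None
    if "group" in df.columns:
        group = {i: g for i, g in df["group"].items() if g}
    calls = df.drop(columns=[c for c in ("sex", "group") if c in df.columns])
    return GenotypeMatrix(calls, sex, locus_class, group)


def write_locus_stats(stats: Sequence[LocusStats], path: str | Path) -> None:
    """Per-locus statistics TSV: locus, MAF, He, Ho, HWE p, n called."""
    with _open_text(path, "wt") as fh:
        fh.write("locus\tmaf\tHe\tHo\thwe_p\tn_called\n")
        for s in stats:
            hwe = f"{s.hwe_p:.6g}" if s.hwe_p is not None else "NA"
            fh.write(
                f"{s.locus}\t{s.maf:.4f}\t{s.He:.4f}\t{s.Ho:.4f}\t{hwe}\t{s.n_called}\n"
            )


def write_dyad_table(reports: Sequence[DyadReport], path: str | Path) -> None:
    """Candidate-dyad report TSV: Ind_1 Ind_2 Sex Hap r_xy 2.5 97.5 P-O."""
    with _open_text(path, "wt") as fh:
        fh.write("Ind_1\tInd_2\tSex\tHap\tr_xy\t2.5\t97.5\tP-O\n")
        for d in reports:
            fh.write(
                "\t".join(
                    [
                        d.ind1,
                        d.ind2,
                        d.sexes,
                        d.haplotype or "NA",
                        f"{d.r:.4f}",
                        f"{d.ci_low:.4f}",
                        f"{d.ci_high:.4f}",
                        d.po_status,
                    ]
                )
                + "\n"
            )


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_report(report, path: str | Path, fmt: str = "json") -> None:
    """Serialize a report with stable key order and fixed float precision,
    so repeated runs produce byte-identical files."""
    if fmt == "json":
        if isinstance(report, FilterReport):
            report = report.to_dict()
        with _open_text(path, "wt") as fh:
            json.dump(_round_floats(report), fh, indent=2)
            fh.write("\n")
    elif fmt == "tsv":
        if not isinstance(report, Sequence) or not all(
            isinstance(d, DyadReport) for d in report
        ):
            raise ValueError("tsv format expects a sequence of DyadReport")
        write_dyad_table(report, path)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
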