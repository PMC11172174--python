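"""Readers and writers for the interchange formats the pipeline touches.

All genomic coordinates inside the package are 0-based half-open. SAM
(1-based) and blast tabular (1-based inclusive) coordinates are converted
at this boundary so no other module ever sees a 1-based number.

Readers validate strictly and raise :class:`FormatError` rather than
silently coercing malformed input.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ClusterInterval",
    "HomologyHit",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_bed",
    "read_blast_tab",
    "read_alignments",
    "write_alignments",
]

DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed input in one of the supported interchange formats."""


@dataclass(frozen=True)
class ClusterInterval:
    """A piRNA-cluster interval on a named reference.

    ``start``/``end`` are 0-based half-open. ``genome_label`` tags the
    genome of origin (e.g. ``"mel"`` or ``"sim"``) so intervals from a
    merged two-species reference stay distinguishable.
    """

    genome_label: str
    chrom: str
    start: int
    end: int
    name: str
    cluster_type: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"interval {self.name!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.cluster_type not in ("uni", "dual", "unknown"):
            raise FormatError(f"unknown cluster_type {self.cluster_type!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HomologyHit:
    """One row of 12-column tabular homology-search output.

    Query/subject coordinates keep the dialect's 1-based inclusive
    convention; they are carried for completeness and are not used as
    genomic coordinates anywhere in the pipeline.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise FormatError(f"negative bitscore for {self.query_id!r}")


def _validate_seq(seq_id: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise FormatError(
            f"record {seq_id!r}: non-DNA characters {sorted(bad)!r}"
        )
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a DNA FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased and restricted to the {A,C,G,T,N} alphabet;
    duplicate ids are rejected.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, _validate_seq(rec.id, str(rec.seq))))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA (60-column wrapping)."""
    seqs = [
        SeqRecord(Seq(_validate_seq(rid, seq)), id=rid, description="")
        for rid, seq in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """Read FASTQ into ``[(id, sequence, phred_qualities), ...]``."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            (
                rec.id,
                _validate_seq(rec.id, str(rec.seq)),
                list(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def read_bed(path: str | Path, genome_label: str) -> list[ClusterInterval]:
    """Read BED3+ cluster intervals, preserving 0-based half-open coords.

    Columns beyond the fourth (name) are ignored except column 5 slot
    reserved-style inputs; a missing name is auto-assigned
    ``interval_<k>``. An optional last column equal to ``uni``/``dual``
    sets the cluster type.
    """
    intervals: list[ClusterInterval] = []
    names: set[str] = set()
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {k + 1}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"line {k + 1}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"line {k + 1}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] else f"interval_{k}"
            if name in names:
                raise FormatError(f"line {k + 1}: duplicate interval name {name!r}")
            names.add(name)
            ctype = "unknown"
            if fields and fields[-1] in ("uni", "dual"):
                ctype = fields[-1]
            intervals.append(
                ClusterInterval(genome_label, chrom, start, end, name, ctype)
            )
    return intervals


def read_blast_tab(path: str | Path) -> list[HomologyHit]:
    """Parse 12-column tabular homology hits, preserving input order."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"line {k + 1}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {k + 1}: {exc}") from exc
    return hits


# --- minimal SAM dialect -------------------------------------------------
#
# Only the fields the pipeline consumes are modelled: QNAME, FLAG (strand
# bit 16 and unmapped bit 4), RNAME, POS (converted to 0-based), SEQ and
# the NM tag. CIGARs other than a single match run are rejected because
# the internal mapper is ungapped. A record without an NM tag is kept but
# its mismatch count is None (flagged unknown).


def read_alignments(path: str | Path):
    """Read the SAM-subset dialect into :class:`hspirna.align.AlignmentRecord`s."""
    from .align import AlignmentRecord  # local import to avoid a cycle

    records = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(f"line {k + 1}: fewer than 11 SAM columns")
            qname, flag_s, rname, pos_s = fields[0], fields[1], fields[2], fields[3]
            cigar, seq = fields[5], fields[9]
            try:
                flag, pos = int(flag_s), int(pos_s)
            except ValueError as exc:
                raise FormatError(f"line {k + 1}: bad FLAG/POS") from exc
            if flag & 4 or rname == "*":
                continue
            if cigar != "*" and not (
                cigar.endswith(("M", "=")) and cigar[:-1].isdigit()
            ):
                raise FormatError(
                    f"line {k + 1}: unsupported CIGAR {cigar!r} (ungapped only)"
                )
            length = len(seq) if seq != "*" else int(cigar[:-1])
            nm = None
            for tag in fields[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            records.append(
                AlignmentRecord(
                    read_id=qname,
                    ref_id=rname,
                    start=pos - 1,
                    strand="-" if flag & 16 else "+",
                    mismatches=nm,
                    length=length,
                )
            )
    return records


def write_alignments(
    records: Sequence,
    path: str | Path,
    reference_lengths: dict[str, int] | None = None,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write alignment records in the SAM-subset dialect.

    ``reference_lengths`` populates @SQ header lines when known;
    ``sequences`` (read_id -> sequence) fills the SEQ column, otherwise
    ``*`` is written and the CIGAR carries the length.
    """
    buf = _stdio.StringIO()
    buf.write("@HD\tVN:1.6\tSO:unsorted\n")
    if reference_lengths:
        for ref, ln in reference_lengths.items():
            buf.write(f"@SQ\tSN:{ref}\tLN:{ln}\n")
    for rec in records:
        flag = 16 if rec.strand == "-" else 0
        seq = sequences.get(rec.read_id, "*") if sequences else "*"
        fields = [
            rec.read_id,
            str(flag),
            rec.ref_id,
            str(rec.start + 1),
            "255",
            f"{rec.length}M",
            "*",
            "0",
            "0",
            seq,
            "*",
        ]
        if rec.mismatches is not None:
            fields.append(f"NM:i:{rec.mismatches}")
        buf.write("\t".join(fields) + "\n")
    Path(path).write_text(buf.getvalue())
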