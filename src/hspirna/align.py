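"""Desk-scale ungapped k-mismatch read mapper.

Short reads (here 19-30 nt small RNAs) are placed on reference sequences
by exhaustive Hamming-distance search, accelerated with a pigeonhole
k-mer seed index: a read with at most ``max_mismatch`` mismatches must
match at least one of ``max_mismatch + 1`` disjoint seeds exactly, so
candidate placements come from seed lookups and are then verified
base-by-base. The result is exactly the set an O(n*m) window scan would
produce; :func:`map_reads_exhaustive` implements that scan directly and
is kept as an independent reference path.

Three placement policies mirror the two mapping modes used for TE and
cluster analysis:

``all_hits``
    every placement within the mismatch budget, on either strand.
``one_best``
    a single minimum-mismatch placement per read with a deterministic
    tie-break (lexicographic ref id, then start, then ``+`` before
    ``-``) - the TE-panel mode.
``best_unique``
    reads whose minimum-mismatch placement is not unique are discarded
    entirely - the species-specificity device used on a merged
    two-genome reference.

``N`` bases mismatch everything, including other ``N`` s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AlignmentParams",
    "AlignmentRecord",
    "map_reads",
    "map_reads_exhaustive",
    "reads_matching",
    "strand_of_te_read",
]

_ENCODE_REF = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# read N encodes differently from reference N so N never matches anything
_ENCODE_READ = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentParams:
    """Mapping policy bundle.

    ``max_mismatch`` is a whole-read Hamming budget (default 3, the
    widest tolerance used anywhere in the pipeline).
    """

    max_mismatch: int = 3
    policy: str = "all_hits"
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.policy not in ("all_hits", "one_best", "best_unique"):
            raise ValueError(f"unknown policy {self.policy!r}")


@dataclass(frozen=True)
class AlignmentRecord:
    """Placement of a read on a named reference.

    ``start`` is the 0-based leftmost reference coordinate of the
    placement; for a ``-`` strand read the biological 5' end sits at
    ``start + length - 1``. ``mismatches`` may be None when a record
    read from an external SAM file lacks an NM tag.
    """

    read_id: str
    ref_id: str
    start: int
    strand: str
    mismatches: int | None
    length: int

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the read's biological 5' end."""
        return self.start if self.strand == "+" else self.start + self.length - 1


class _RefIndex:
    """Exact k-mer position index over one reference sequence."""

    def __init__(self, ref_id: str, seq: str, k: int):
        self.ref_id = ref_id
        self.seq = seq
        self.k = k
        self.arr = np.fromiter(
            (_ENCODE_REF[c] for c in seq), dtype=np.uint8, count=len(seq)
        )
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        self.index = {km: np.asarray(v, dtype=np.int64) for km, v in index.items()}

    def candidates(self, read: str, max_mm: int) -> np.ndarray:
        """Candidate start positions from pigeonhole seed lookups."""
        L, k = len(read), self.k
        n_seeds = max_mm + 1
        if n_seeds * k > L:  # fall back to all windows (tiny read)
            return np.arange(max(0, len(self.seq) - L + 1), dtype=np.int64)
        # disjoint seeds spread across the read
        if n_seeds == 1:
            offsets = [0]
        else:
            step = max(k, (L - k) // (n_seeds - 1))
            offsets = [min(i * step, L - k) for i in range(n_seeds)]
        cands: list[np.ndarray] = []
        for off in offsets:
            pos = self.index.get(read[off : off + k])
            if pos is not None:
                cands.append(pos - off)
        if not cands:
            return np.empty(0, dtype=np.int64)
        starts = np.unique(np.concatenate(cands))
        return starts[(starts >= 0) & (starts <= len(self.seq) - L)]

    def verify(self, read_arr: np.ndarray, starts: np.ndarray, max_mm: int):
        """Hamming-verify candidate starts; returns (starts, mismatches)."""
        if starts.size == 0:
            return starts, starts
        L = read_arr.size
        windows = self.arr[starts[:, None] + np.arange(L)[None, :]]
        mm = (windows != read_arr[None, :]).sum(axis=1)
        keep = mm <= max_mm
        return starts[keep], mm[keep]


def _encode_read(seq: str) -> np.ndarray:
    return np.fromiter(
        (_ENCODE_READ[c] for c in seq), dtype=np.uint8, count=len(seq)
    )


def _hits_for_seq(
    seq: str, indexes: Sequence[_RefIndex], params: AlignmentParams
) -> list[tuple[str, int, str, int]]:
    """All (ref_id, start, strand, mismatches) placements for one sequence."""
    hits: list[tuple[str, int, str, int]] = []
    strands = [("+", seq)]
    if params.both_strands:
        strands.append(("-", revcomp(seq)))
    for strand, s in strands:
        arr = _encode_read(s)
        for idx in indexes:
            if len(s) > len(idx.seq):
                continue
            starts = idx.candidates(s, params.max_mismatch)
            starts, mm = idx.verify(arr, starts, params.max_mismatch)
            hits.extend(
                (idx.ref_id, int(st), strand, int(m)) for st, m in zip(starts, mm)
            )
    return hits


_STRAND_ORDER = {"+": 0, "-": 1}


def _apply_policy(
    hits: list[tuple[str, int, str, int]], policy: str
) -> list[tuple[str, int, str, int]]:
    if policy == "all_hits" or not hits:
        return sorted(hits, key=lambda h: (h[0], h[1], _STRAND_ORDER[h[2]]))
    best = min(h[3] for h in hits)
    best_hits = sorted(
        (h for h in hits if h[3] == best),
        key=lambda h: (h[0], h[1], _STRAND_ORDER[h[2]]),
    )
    if policy == "one_best":
        return best_hits[:1]
    # best_unique: drop the read if its best placement is ambiguous
    return best_hits if len(best_hits) == 1 else []


def build_indexes(
    references: Iterable[tuple[str, str]], max_mismatch: int, min_read_len: int
) -> list[_RefIndex]:
    k = max(4, min_read_len // (max_mismatch + 1))
    k = min(k, min_read_len)
    return [_RefIndex(rid, seq.upper(), k) for rid, seq in references]


def map_reads(
    reads: Sequence[tuple[str, str]],
    references: Sequence[tuple[str, str]],
    params: AlignmentParams | None = None,
) -> list[AlignmentRecord]:
    """Map reads onto references under the given policy.

    Identical read sequences are collapsed internally and mapped once;
    every read id still yields its own records, so abundance carried by
    duplicated reads is preserved downstream.
    """
    params = params or AlignmentParams()
    if not references:
        raise ValueError("empty reference set")
    if not reads:
        return []
    min_len = min(len(seq) for _, seq in reads)
    indexes = build_indexes(references, params.max_mismatch, min_len)

    by_seq: dict[str, list[str]] = {}
    order: dict[str, int] = {}
    for i, (rid, seq) in enumerate(reads):
        seq = seq.upper()
        by_seq.setdefault(seq, []).append(rid)
        order.setdefault(rid, i)

    records: list[AlignmentRecord] = []
    for seq, rids in by_seq.items():
        hits = _apply_policy(_hits_for_seq(seq, indexes, params), params.policy)
        for rid in rids:
            records.extend(
                AlignmentRecord(rid, ref, st, strand, mm, len(seq))
                for ref, st, strand, mm in hits
            )
    records.sort(
        key=lambda r: (order[r.read_id], r.ref_id, r.start, _STRAND_ORDER[r.strand])
    )
    return records


def map_reads_exhaustive(
    reads: Sequence[tuple[str, str]],
    references: Sequence[tuple[str, str]],
    params: AlignmentParams | None = None,
) -> list[AlignmentRecord]:
    """Reference implementation: plain O(n*m) window scan, no index.

    Kept deliberately simple and separate from :func:`map_reads` so the
    two can be compared on any instance.
    """
    params = params or AlignmentParams()
    if not references:
        raise ValueError("empty reference set")
    records: list[AlignmentRecord] = []
    for pos_in_input, (rid, seq) in enumerate(reads):
        seq = seq.upper()
        hits: list[tuple[str, int, str, int]] = []
        strands = [("+", seq)]
        if params.both_strands:
            strands.append(("-", revcomp(seq)))
        for ref_id, ref in references:
            ref = ref.upper()
            for strand, s in strands:
                for start in range(len(ref) - len(s) + 1):
                    window = ref[start : start + len(s)]
                    mm = sum(
                        1
                        for a, b in zip(window, s)
                        if a != b or a == "N" or b == "N"
                    )
                    if mm <= params.max_mismatch:
                        hits.append((ref_id, start, strand, mm))
        for ref, st, strand, mm in _apply_policy(hits, params.policy):
            records.append(AlignmentRecord(rid, ref, st, strand, mm, len(seq)))
    return records


def reads_matching(
    reads: Sequence[tuple[str, str]],
    references: Sequence[tuple[str, str]],
    max_mismatch: int,
) -> np.ndarray:
    """Boolean mask over reads: True where the read aligns anywhere in
    ``references`` (either strand, ungapped, <= max_mismatch).

    This is the primitive behind contaminant and miRNA filtering.
    """
    if not references or not reads:
        return np.zeros(len(reads), dtype=bool)
    params = AlignmentParams(max_mismatch=max_mismatch, policy="all_hits")
    min_len = min(len(seq) for _, seq in reads)
    indexes = build_indexes(references, max_mismatch, min_len)
    cache: dict[str, bool] = {}
    mask = np.zeros(len(reads), dtype=bool)
    for i, (_, seq) in enumerate(reads):
        seq = seq.upper()
        if seq not in cache:
            cache[seq] = bool(_hits_for_seq(seq, indexes, params))
        mask[i] = cache[seq]
    return mask


def strand_of_te_read(record: AlignmentRecord) -> str:
    """Orient a TE-mapped read: ``+`` placements are sense (TE consensus
    sequences are stored in their sense orientation), ``-`` antisense."""
    return "sense" if record.strand == "+" else "antisense"
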