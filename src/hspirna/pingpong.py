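"""5'-to-5' overlap histograms and the z10 ping-pong statistic.

Secondary piRNA biogenesis (the ping-pong cycle) leaves a geometric
footprint: sense and antisense piRNAs whose 5' ends overlap by exactly
10 nt. For a sense read with 5' end at reference coordinate ``p``
(= its start) and an antisense read with 5' end at ``q`` (= start +
length - 1), the overlap is ``o = q - p + 1``; a perfect ping-pong pair
gives o = 10. The histogram counts pairs for o in 1..30 and the z10
score standardizes bin 10 against the other 29 bins (sample SD).

Pair counting is exhaustive over read pairs with abundance weighting (a
read seen c times contributes c to every pairing); mismatch counts of
the underlying alignments do not weight pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import AlignmentRecord

__all__ = [
    "MAX_OVERLAP",
    "OverlapHistogram",
    "PingPongScore",
    "overlap_histogram",
    "zscore",
    "cross_pingpong",
]

MAX_OVERLAP = 30


@dataclass
class OverlapHistogram:
    """Counts of 5'-to-5' sense/antisense overlaps of 1..30 nt.

    ``counts[o]`` for o in 1..30 is the (abundance-weighted) number of
    read pairs at that overlap; ``normalized`` divides by the total
    piRNA count on the reference, matching the convention of reporting
    overlapping pairs per piRNA.
    """

    counts: dict[int, float]
    n_pairs_total: float
    total_reads: float

    @property
    def normalized(self) -> dict[int, float]:
        if self.total_reads == 0:
            return {o: 0.0 for o in self.counts}
        return {o: c / self.total_reads for o, c in self.counts.items()}

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[o] for o in range(1, MAX_OVERLAP + 1)])


@dataclass(frozen=True)
class PingPongScore:
    """z10 statistic with its background moments.

    ``defined`` is False (and ``z10`` None) when the histogram carries
    no signal to standardize against (all-zero, or zero background SD
    with an off-mean bin 10).
    """

    z10: float | None
    background_mean: float
    background_sd: float
    defined: bool
    note: str = ""


def _position_weights(
    alignments: Sequence[AlignmentRecord],
    weights: Mapping[str, float] | None,
) -> tuple[dict[int, float], dict[int, float], float]:
    """Per-position 5'-end weight vectors for sense (+) and antisense (-)."""
    sense: dict[int, float] = {}
    anti: dict[int, float] = {}
    total = 0.0
    for rec in alignments:
        w = 1.0 if weights is None else float(weights.get(rec.read_id, 1.0))
        total += w
        if rec.strand == "+":
            sense[rec.five_prime] = sense.get(rec.five_prime, 0.0) + w
        else:
            anti[rec.five_prime] = anti.get(rec.five_prime, 0.0) + w
    return sense, anti, total


def _check_single_reference(*alignment_sets: Sequence[AlignmentRecord]) -> None:
    refs = {rec.ref_id for recs in alignment_sets for rec in recs}
    if len(refs) > 1:
        raise ValueError(
            f"alignments span multiple references {sorted(refs)!r}; "
            "restrict to one reference first"
        )


def _pair_counts(
    sense: dict[int, float], anti: dict[int, float]
) -> dict[int, float]:
    counts = {o: 0.0 for o in range(1, MAX_OVERLAP + 1)}
    for q, wa in anti.items():
        for o in range(1, MAX_OVERLAP + 1):
            ws = sense.get(q - o + 1)
            if ws:
                counts[o] += ws * wa
    return counts


def overlap_histogram(
    alignments: Sequence[AlignmentRecord],
    weights: Mapping[str, float] | None = None,
) -> OverlapHistogram:
    """Histogram of 5'-to-5' overlaps among alignments on one reference.

    ``weights`` maps read_id -> abundance (default 1 per record).
    """
    _check_single_reference(alignments)
    sense, anti, total = _position_weights(alignments, weights)
    counts = _pair_counts(sense, anti)
    return OverlapHistogram(counts, sum(counts.values()), total)


def cross_pingpong(
    set_a: Sequence[AlignmentRecord],
    set_b: Sequence[AlignmentRecord],
    weights: Mapping[str, float] | None = None,
) -> tuple[OverlapHistogram, PingPongScore]:
    """Ping-pong signature restricted to pairs with one member from each
    set (either strand arrangement), both mapped on the same reference.

    Used for cross-locus signatures, e.g. cluster-derived piRNAs (set A)
    against piRNAs mapped on a target transcript (set B). Symmetric in
    its two arguments.
    """
    _check_single_reference(set_a, set_b)
    refs_a = {r.ref_id for r in set_a}
    refs_b = {r.ref_id for r in set_b}
    if refs_a and refs_b and refs_a != refs_b:
        raise ValueError("the two sets are mapped on disjoint references")
    sense_a, anti_a, tot_a = _position_weights(set_a, weights)
    sense_b, anti_b, tot_b = _position_weights(set_b, weights)
    ab = _pair_counts(sense_a, anti_b)
    ba = _pair_counts(sense_b, anti_a)
    counts = {o: ab[o] + ba[o] for o in ab}
    hist = OverlapHistogram(counts, sum(counts.values()), tot_a + tot_b)
    return hist, zscore(hist)


def zscore(
    hist: OverlapHistogram, include_focal_in_background: bool = False
) -> PingPongScore:
    """z10 = (counts[10] - mean(background)) / sd(background).

    Background is bins 1..30 excluding 10 (the standard construction;
    including bin 10 only shrinks the score and is exposed via
    ``include_focal_in_background``). Sample SD (ddof=1). Degenerate
    histograms yield an undefined, flagged score rather than an error.
    """
    arr = hist.as_array()
    focal = arr[9]
    if include_focal_in_background:
        background = arr
    else:
        background = np.delete(arr, 9)
    if not np.any(arr):
        return PingPongScore(None, 0.0, 0.0, False, "empty histogram")
    mean = float(background.mean())
    sd = float(background.std(ddof=1))
    if sd == 0.0:
        if focal == mean:
            return PingPongScore(0.0, mean, 0.0, True, "flat histogram")
        return PingPongScore(
            None, mean, 0.0, False, "zero background SD with off-mean bin 10"
        )
    return PingPongScore(float((focal - mean) / sd), mean, sd, True)
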