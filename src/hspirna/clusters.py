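"""piRNA-cluster activity via unique mapping on a merged reference.

Repetitive piRNA clusters cannot be quantified with multi-mapping
reads; activity is therefore measured with reads that map uniquely -
zero mismatches, best placement unique - on a merged reference carrying
both parental genomes, which simultaneously enforces species
specificity (a read occurring verbatim in both genomes is discarded).
A read is assigned to a cluster interval when its 5' end lies inside
the interval (single unambiguous rule for boundary reads; full
containment available via ``full_containment``).

The expected hybrid/parent activity ratio for a single-copy inherited
cluster is 0.5 (one genome copy in the hybrid versus two in the
parent).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentParams, AlignmentRecord, map_reads
from .io import ClusterInterval
from .smallrna import ReadLibrary, rpm

__all__ = [
    "EXPECTED_HYBRID_RATIO",
    "cluster_activity",
    "relative_activity",
    "coverage_track",
]

EXPECTED_HYBRID_RATIO = 0.5

_UNIQUE_PARAMS = AlignmentParams(max_mismatch=0, policy="best_unique")


def cluster_activity(
    reads: Sequence[tuple[str, str]],
    references: Sequence[tuple[str, str]],
    intervals: Sequence[ClusterInterval],
    lib: ReadLibrary,
    full_containment: bool = False,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Unique-mapping piRNA activity per cluster interval.

    ``references`` is the merged set (both genomes); ``lib`` provides
    the rpm denominator. Returns a DataFrame indexed by interval name
    with unique counts, sense/antisense split (relative to the +
    strand of the interval's reference) and rpm columns.
    """
    ref_ids = {rid for rid, _ in references}
    for iv in intervals:
        if iv.chrom not in ref_ids:
            raise ValueError(f"interval {iv.name!r}: chromosome {iv.chrom!r} "
                             "missing from the merged reference")
    records = map_reads(list(reads), list(references), _UNIQUE_PARAMS)

    rows = {}
    for iv in intervals:
        sense = anti = 0.0
        for rec in records:
            if rec.ref_id != iv.chrom:
                continue
            if full_containment:
                inside = iv.start <= rec.start and rec.start + rec.length <= iv.end
            else:
                inside = iv.start <= rec.five_prime < iv.end
            if not inside:
                continue
            w = 1.0 if weights is None else float(weights.get(rec.read_id, 1.0))
            if rec.strand == "+":
                sense += w
            else:
                anti += w
        rows[iv.name] = {
            "genome_label": iv.genome_label,
            "cluster_type": iv.cluster_type,
            "sense_count": sense,
            "antisense_count": anti,
            "unique_count": sense + anti,
            "sense_rpm": rpm(sense, lib),
            "antisense_rpm": rpm(anti, lib),
            "unique_rpm": rpm(sense + anti, lib),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cluster"
    return out


def relative_activity(
    hybrid_activity: pd.DataFrame,
    parent_activity: pd.DataFrame,
    column: str = "unique_rpm",
) -> pd.Series:
    """Per-cluster hybrid/parent rpm ratio (NaN where the parent is 0).

    Compare against :data:`EXPECTED_HYBRID_RATIO` (0.5), the expected
    level for a heterozygous single-copy cluster.
    """
    parent = parent_activity[column]
    ratio = hybrid_activity[column] / parent.where(parent > 0)
    ratio.name = "hybrid_to_parent_ratio"
    return ratio


def coverage_track(
    reads: Sequence[tuple[str, str]],
    references: Sequence[tuple[str, str]],
    interval: ClusterInterval,
) -> pd.DataFrame:
    """Per-position sense/antisense unique-read coverage inside one
    interval (track-style output)."""
    records = map_reads(list(reads), list(references), _UNIQUE_PARAMS)
    length = len(interval)
    sense = np.zeros(length)
    anti = np.zeros(length)
    for rec in records:
        if rec.ref_id != interval.chrom:
            continue
        lo = max(rec.start, interval.start) - interval.start
        hi = min(rec.start + rec.length, interval.end) - interval.start
        if hi <= lo:
            continue
        (sense if rec.strand == "+" else anti)[lo:hi] += 1
    return pd.DataFrame(
        {
            "position": np.arange(interval.start, interval.end),
            "sense": sense,
            "antisense": anti,
        }
    )
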