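"""Small-RNA read-processing cascade with explicit depth bookkeeping.

The pipeline mirrors the standard ovary small-RNA workflow: adapter
trimming, (optional) quality filtering, removal of structural-RNA
contaminants (rRNA/snRNA/snoRNA/tRNA), removal of miRNAs, and selection
of the 23-29 nt piRNA fraction. Each stage records the surviving read
count so normalization can refer to a well-defined library depth.

The rpm denominator is the depth *before* miRNA filtration (i.e. after
contaminant removal): miRNAs are genuine cellular small RNAs, so they
belong in the sequencing-depth denominator even though they are removed
from the piRNA fraction. ``norm_stage`` on :func:`process_library`
overrides this (e.g. ``"raw"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import align

__all__ = [
    "STAGES",
    "ReadLibrary",
    "trim_adapter",
    "filter_quality",
    "filter_contaminants",
    "filter_mirna",
    "select_length",
    "rpm",
    "process_library",
]

STAGES = (
    "raw",
    "adapter_trimmed",
    "quality_kept",
    "contaminant_filtered",
    "mirna_filtered",
    "length_selected",
)

DEFAULT_NORM_STAGE = "contaminant_filtered"


@dataclass
class ReadLibrary:
    """A small-RNA read collection with per-stage depth bookkeeping.

    ``stage_depths`` maps each completed stage to the read count after
    it; depths are non-increasing along :data:`STAGES`.
    ``normalization_depth`` is the depth at the stage rpm normalizes to.
    """

    reads: list[tuple[str, str]]
    stage_depths: dict[str, int] = field(default_factory=dict)
    norm_stage: str = DEFAULT_NORM_STAGE

    def __post_init__(self) -> None:
        if not self.stage_depths:
            self.stage_depths = {"raw": len(self.reads)}

    def record_stage(self, stage: str) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        prev = list(self.stage_depths.values())
        if prev and len(self.reads) > prev[-1]:
            raise ValueError("stage depths must be non-increasing")
        self.stage_depths[stage] = len(self.reads)

    @property
    def normalization_depth(self) -> int:
        if self.norm_stage not in self.stage_depths:
            raise ValueError(
                f"normalization stage {self.norm_stage!r} not yet recorded"
            )
        return self.stage_depths[self.norm_stage]

    def replaced(self, reads: list[tuple[str, str]]) -> "ReadLibrary":
        return ReadLibrary(reads, dict(self.stage_depths), self.norm_stage)


def trim_adapter(
    reads: Sequence[tuple[str, str]], adapter: str, min_overlap: int = 3
) -> list[tuple[str, str]]:
    """Remove 3' adapter sequence from each read.

    The longest read suffix exactly matching a prefix of ``adapter``
    (length >= min_overlap) is removed; reads trimmed to length 0 are
    dropped. Exact matching only - synthetic inputs are error-free and
    tolerance would be a calibration knob, not a different algorithm.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = adapter.upper()
    out: list[tuple[str, str]] = []
    for rid, seq in reads:
        seq = seq.upper()
        cut = len(seq)
        # earliest i gives the longest suffix; the suffix must equal a
        # prefix of the adapter (read may end mid-adapter)
        for i in range(len(seq) - min_overlap + 1):
            tail = seq[i:]
            if len(tail) <= len(adapter) and adapter.startswith(tail):
                cut = i
                break
        trimmed = seq[:cut]
        if trimmed:
            out.append((rid, trimmed))
    return out


def filter_quality(
    reads: Sequence[tuple[str, str]],
    qualities: dict[str, Sequence[int]] | None,
    min_mean_quality: float = 30.0,
) -> list[tuple[str, str]]:
    """Drop reads whose mean phred quality is <= min_mean_quality.

    FASTA inputs carry no qualities (``qualities=None``): pass-through.
    """
    if qualities is None:
        return list(reads)
    out = []
    for rid, seq in reads:
        q = qualities.get(rid)
        if q is None or (sum(q) / len(q)) > min_mean_quality:
            out.append((rid, seq))
    return out


def _filter_against(
    lib: ReadLibrary,
    refs: Sequence[tuple[str, str]],
    max_mismatch: int,
    stage: str,
) -> ReadLibrary:
    if not refs:
        import warnings

        warnings.warn(f"empty reference set for stage {stage}; pass-through")
        new = lib.replaced(list(lib.reads))
        new.record_stage(stage)
        return new
    mask = align.reads_matching(lib.reads, refs, max_mismatch)
    survivors = [r for r, hit in zip(lib.reads, mask) if not hit]
    new = lib.replaced(survivors)
    new.record_stage(stage)
    return new


def filter_contaminants(
    lib: ReadLibrary,
    contaminant_refs: Sequence[tuple[str, str]],
    max_mismatch: int = 3,
) -> ReadLibrary:
    """Remove reads aligning anywhere in rRNA/snRNA/snoRNA/tRNA
    references (either strand, ungapped, <= max_mismatch)."""
    return _filter_against(lib, contaminant_refs, max_mismatch, "contaminant_filtered")


def filter_mirna(
    lib: ReadLibrary,
    mirna_refs: Sequence[tuple[str, str]],
    max_mismatch: int = 3,
) -> ReadLibrary:
    """Remove miRNA-matching reads. Does not touch the normalization
    depth: rpm stays anchored to the pre-miRNA-filtration library."""
    return _filter_against(lib, mirna_refs, max_mismatch, "mirna_filtered")


def select_length(
    lib: ReadLibrary, min_nt: int = 23, max_nt: int = 29
) -> ReadLibrary:
    """Keep reads with min_nt <= length <= max_nt (both ends inclusive,
    the piRNA-sized fraction)."""
    if min_nt > max_nt:
        raise ValueError(f"min_nt {min_nt} > max_nt {max_nt}")
    new = lib.replaced(
        [(rid, s) for rid, s in lib.reads if min_nt <= len(s) <= max_nt]
    )
    new.record_stage("length_selected")
    return new


def rpm(count: float, lib: ReadLibrary) -> float:
    """Reads-per-million: count / normalization_depth * 1e6."""
    if count < 0:
        raise ValueError("count must be non-negative")
    depth = lib.normalization_depth
    if depth <= 0:
        raise ValueError("normalization depth is zero; rpm undefined")
    return count / depth * 1e6


def process_library(
    reads: Sequence[tuple[str, str]],
    adapter: str | None = None,
    qualities: dict[str, Sequence[int]] | None = None,
    contaminant_refs: Sequence[tuple[str, str]] = (),
    mirna_refs: Sequence[tuple[str, str]] = (),
    min_nt: int = 23,
    max_nt: int = 29,
    max_mismatch: int = 3,
    min_overlap: int = 3,
    norm_stage: str = DEFAULT_NORM_STAGE,
) -> ReadLibrary:
    """Run the full cascade and return the length-selected library with
    all stage depths recorded."""
    lib = ReadLibrary([(r, s.upper()) for r, s in reads], norm_stage=norm_stage)
    trimmed = (
        trim_adapter(lib.reads, adapter, min_overlap) if adapter else list(lib.reads)
    )
    lib = lib.replaced(trimmed)
    lib.record_stage("adapter_trimmed")
    lib = lib.replaced(filter_quality(lib.reads, qualities))
    lib.record_stage("quality_kept")
    lib = filter_contaminants(lib, contaminant_refs, max_mismatch)
    lib = filter_mirna(lib, mirna_refs, max_mismatch)
    lib = select_length(lib, min_nt, max_nt)
    return lib
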