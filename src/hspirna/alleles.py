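"""Ortholog resolution and allele-specific expression in hybrids.

An F1 hybrid carries one copy of each parental allele, so the neutral
expectation for an allele is half its (two-copy) parental level. Each
ortholog pair is scored by two ratios - hybrid allele / same-species
parent, on depth-normalized values with a 0.5 pseudocount - and
classified against the half-dose expectation with a symmetric band of
``band_log2`` (default 1.0, i.e. within twofold of the expected half
level, matching the twofold convention used for gene-level DE calls).

Ortholog pairs come from tabular homology hits: per query transcript
the top-bitscore hit wins (ties break to the lexicographically smaller
subject and are conflict-flagged), and a gene pair is accepted only if
all transcripts of the gene agree on a single subject gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import pingpong
from .align import AlignmentParams, AlignmentRecord, map_reads
from .destats import size_factors
from .io import HomologyHit
from .smallrna import ReadLibrary

__all__ = [
    "DOSAGE_BAND_LOG2",
    "EXPECTED_ALLELE_RATIO",
    "OrthologPair",
    "resolve_orthologs",
    "allele_expression",
    "classify_dosage",
    "category_frequencies",
    "expression_correlation",
    "vasa_atchx_report",
]

EXPECTED_ALLELE_RATIO = 0.5  # half-dose: one allele copy vs two in the parent
DOSAGE_BAND_LOG2 = 1.0
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class OrthologPair:
    gene_mel: str
    gene_sim: str
    support: int  # transcripts agreeing on the pairing
    conflict: bool
    accepted: bool


def resolve_orthologs(
    hits: Sequence[HomologyHit],
    tx2gene_mel: Mapping[str, str],
    tx2gene_sim: Mapping[str, str],
) -> list[OrthologPair]:
    """Resolve gene-level ortholog pairs from transcript-level hits.

    Rejections keep a record (``accepted=False``) so acceptance rates
    can be audited. A subject gene claimed by several query genes is
    kept only for the claimant with the highest summed best-hit
    bitscore; the others are conflict-rejected, so every gene appears in
    at most one accepted pair.
    """
    if not hits:
        raise ValueError("no homology hits supplied")
    best: dict[str, tuple[float, str, bool]] = {}
    for h in hits:
        if h.query_id not in tx2gene_mel:
            raise KeyError(f"query transcript {h.query_id!r} missing from gene map")
        if h.subject_id not in tx2gene_sim:
            raise KeyError(f"subject transcript {h.subject_id!r} missing from gene map")
        cur = best.get(h.query_id)
        if cur is None or h.bitscore > cur[0]:
            best[h.query_id] = (h.bitscore, h.subject_id, False)
        elif h.bitscore == cur[0] and h.subject_id != cur[1]:
            winner = min(h.subject_id, cur[1])
            best[h.query_id] = (h.bitscore, winner, True)

    by_gene: dict[str, list[tuple[str, float, bool]]] = {}
    for tx, (score, subj_tx, tied) in best.items():
        by_gene.setdefault(tx2gene_mel[tx], []).append(
            (tx2gene_sim[subj_tx], score, tied)
        )

    provisional: list[tuple[str, str, int, bool, float]] = []
    for gene, assignments in sorted(by_gene.items()):
        targets = {t for t, _, _ in assignments}
        tied_any = any(tied for _, _, tied in assignments)
        if len(targets) == 1:
            target = next(iter(targets))
            provisional.append(
                (gene, target, len(assignments), tied_any,
                 sum(s for _, s, _ in assignments))
            )
        else:
            # transcripts disagree on the subject gene: reject
            top = max(assignments, key=lambda a: a[1])
            provisional.append((gene, top[0], len(assignments), True, -1.0))

    claimed: dict[str, tuple[str, float]] = {}
    for gene, target, _, conflict, score in provisional:
        if conflict:
            continue
        prev = claimed.get(target)
        if prev is None or score > prev[1]:
            claimed[target] = (gene, score)

    pairs = []
    for gene, target, support, conflict, score in provisional:
        unique = not conflict and claimed[target][0] == gene
        pairs.append(
            OrthologPair(gene, target, support, conflict or not unique,
                         accepted=unique and not conflict)
        )
    return pairs


def _hybrid_sample_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors with the two hybrid allele groups summed
    into whole-hybrid samples (they come from one library)."""
    groups = counts.columns.get_level_values("group")
    mel_p = counts.loc[:, groups == "mel_parent"]
    sim_p = counts.loc[:, groups == "sim_parent"]
    hyb = (
        counts.loc[:, groups == "hybrid_mel_allele"].to_numpy()
        + counts.loc[:, groups == "hybrid_sim_allele"].to_numpy()
    )
    mat = np.hstack([mel_p.to_numpy(), sim_p.to_numpy(), hyb])
    sf = size_factors(mat)
    n = mel_p.shape[1]
    labels = (
        [("mel_parent", r) for r in range(1, n + 1)]
        + [("sim_parent", r) for r in range(1, n + 1)]
        + [("hybrid", r) for r in range(1, n + 1)]
    )
    return pd.Series(sf, index=pd.MultiIndex.from_tuples(labels))


def allele_expression(
    counts: pd.DataFrame,
    pairs: Sequence[OrthologPair] | None = None,
) -> pd.DataFrame:
    """Per-gene allele-specific expression table.

    ``counts`` is the allele-resolved matrix (genes x (group, replicate)
    with groups mel_parent / sim_parent / hybrid_mel_allele /
    hybrid_sim_allele). When ``pairs`` is given, only accepted pairs are
    scored (rejected ones are skipped). Expression values are
    depth-normalized replicate means; ratios carry a 0.5 pseudocount.
    """
    sf = _hybrid_sample_factors(counts)
    n_rep = counts.columns.get_level_values("replicate").nunique()

    def norm_mean(group: str, factor_group: str) -> np.ndarray:
        block = counts.loc[:, counts.columns.get_level_values("group") == group]
        f = sf.loc[factor_group].to_numpy()
        return (block.to_numpy() / f).mean(axis=1)

    table = pd.DataFrame(
        {
            "parent_mel": norm_mean("mel_parent", "mel_parent"),
            "parent_sim": norm_mean("sim_parent", "sim_parent"),
            "hybrid_mel": norm_mean("hybrid_mel_allele", "hybrid"),
            "hybrid_sim": norm_mean("hybrid_sim_allele", "hybrid"),
        },
        index=counts.index,
    )
    if pairs is not None:
        keep = [p.gene_mel for p in pairs if p.accepted]
        table = table.loc[table.index.intersection(keep)]
    table["ratio_mel"] = (table["hybrid_mel"] + PSEUDOCOUNT) / (
        table["parent_mel"] + PSEUDOCOUNT
    )
    table["ratio_sim"] = (table["hybrid_sim"] + PSEUDOCOUNT) / (
        table["parent_sim"] + PSEUDOCOUNT
    )
    table["category"] = [
        classify_dosage(rm, rs) for rm, rs in zip(table["ratio_mel"], table["ratio_sim"])
    ]
    return table


def _allele_call(ratio: float, band_log2: float) -> str:
    center = np.log2(EXPECTED_ALLELE_RATIO)
    lr = np.log2(ratio) if ratio > 0 else -np.inf
    if lr > center + band_log2:
        return "over"
    if lr < center - band_log2:
        return "under"
    return "expected"


def classify_dosage(
    ratio_mel: float, ratio_sim: float, band_log2: float = DOSAGE_BAND_LOG2
) -> str:
    """Dosage category from the two hybrid/parent allele ratios.

    Each allele is called over/under/expected against the half-dose
    expectation with a +/- band_log2 band; the pair of calls maps to
    expected / one_allele_over / both_over / both_under / mixed_other.
    """
    calls = {_allele_call(ratio_mel, band_log2), _allele_call(ratio_sim, band_log2)}
    if calls == {"expected"}:
        return "expected"
    if calls == {"over", "expected"}:
        return "one_allele_over"
    if calls == {"over"}:
        return "both_over"
    if calls == {"under"}:
        return "both_under"
    return "mixed_other"


def category_frequencies(table: pd.DataFrame) -> pd.Series:
    """Fractions of each dosage category in an allele-expression table."""
    return table["category"].value_counts(normalize=True)


def expression_correlation(
    hybrid_expr, parent_expr, pseudocount: float = PSEUDOCOUNT
) -> float | None:
    """Pearson r between log2(hybrid) and log2(parent) expression.

    Returns None when either log-vector has zero variance.
    """
    x = np.log2(np.asarray(hybrid_expr, dtype=float) + pseudocount)
    y = np.log2(np.asarray(parent_expr, dtype=float) + pseudocount)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def vasa_atchx_report(
    cluster_reads: Sequence[tuple[str, str]],
    allele_reads: Mapping[str, Sequence[tuple[str, str]]],
    alleles: Mapping[str, tuple[str, str]],
    consensus: tuple[str, str],
    region_offset: Mapping[str, int],
    max_mismatch: int = 3,
    weights: Mapping[str, float] | None = None,
) -> dict[str, dict]:
    """Cross ping-pong between repeat-cluster piRNAs and allele-mapped
    piRNAs, per species-specific allele.

    For each allele transcript, cluster-derived reads and allele-derived
    reads are independently mapped onto the transcript (ungapped,
    <= max_mismatch); the ping-pong histogram is built only from pairs
    with one member from each set. Divergence between the repeat
    consensus and an allele beyond the mismatch budget empties the
    cluster-mapped set, which is the species-specificity readout.

    Returns {allele_label: {"z10": PingPongScore, "histogram":
    OverlapHistogram, "coverage": DataFrame, "n_cluster_alignments": int}}.
    """
    cons_id, cons_seq = consensus
    report: dict[str, dict] = {}
    params = AlignmentParams(max_mismatch=max_mismatch, policy="one_best")
    for label, (tx_id, tx_seq) in alleles.items():
        off = region_offset[label]
        if off < 0 or off + len(cons_seq) > len(tx_seq):
            raise ValueError(
                f"consensus {cons_id!r} does not fit in transcript {tx_id!r} "
                f"at offset {off}"
            )
        refs = [(tx_id, tx_seq)]
        cluster_aln = map_reads(list(cluster_reads), refs, params)
        allele_aln = map_reads(list(allele_reads[label]), refs, params)
        hist, score = pingpong.cross_pingpong(cluster_aln, allele_aln, weights)
        cov = _coverage(cluster_aln + allele_aln, len(tx_seq), weights)
        report[label] = {
            "z10": score,
            "histogram": hist,
            "coverage": cov,
            "n_cluster_alignments": len(cluster_aln),
        }
    return report


def _coverage(
    alignments: Sequence[AlignmentRecord],
    length: int,
    weights: Mapping[str, float] | None,
) -> pd.DataFrame:
    sense = np.zeros(length)
    anti = np.zeros(length)
    for rec in alignments:
        w = 1.0 if weights is None else float(weights.get(rec.read_id, 1.0))
        track = sense if rec.strand == "+" else anti
        track[rec.start : rec.start + rec.length] += w
    return pd.DataFrame({"position": np.arange(length), "sense": sense, "antisense": anti})
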