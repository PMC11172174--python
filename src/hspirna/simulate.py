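"""Synthetic-data generators for every stage of the pipeline.

The generators emulate the statistical structure of the real study
design - two diverged parental transcriptomes with orthologous genes, a
hybrid carrying one allele of each, a panel of TE consensus sequences
with sense/antisense piRNA populations and a tunable fraction of exact
10-nt 5'-overlap ping-pong pairs, contaminant (rRNA- and miRNA-like)
reads, and negative-binomial mRNA counts with planted allele-dosage
categories - so the whole analysis runs deterministically from integer
seeds without external downloads.

Ground truth (read origin, strand, ping-pong pairing, planted dosage
category) is retained alongside every simulated object so recovery can
be checked exactly.

Orthologous sequences differ by substitutions only (no indels), keeping
paired coordinates aligned 1:1. Ping-pong pairs are built by
construction - the antisense 5' end is placed 10 nt into a sense read's
span - because the downstream statistic depends only on 5'-5' geometry.
piRNA 5' ends are placed uniformly along each consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import revcomp
from .io import ClusterInterval, HomologyHit
from .smallrna import STAGES, ReadLibrary

__all__ = [
    "TEFamily",
    "SpeciesPair",
    "PiRNAScenario",
    "SimulatedLibrary",
    "DosagePlan",
    "ClusterScenario",
    "AtChXScenario",
    "generate_species_pair",
    "make_te_panel",
    "simulate_small_rna_library",
    "simulate_rnaseq_counts",
    "simulate_homology_hits",
    "simulate_cluster_scenario",
    "simulate_atchx_scenario",
]

BASES = np.array(list("ACGT"))

DOSAGE_CATEGORIES = (
    "expected",
    "one_allele_over",
    "both_over",
    "both_under",
    "mixed_other",
)

#: 3' adapter appended to simulated raw reads (standard small-RNA kit adapter)
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each site with probability ``rate`` (never to itself)."""
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        codes = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(codes + shifts) % 4]
    return "".join(arr)


def _mutate_evenly(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute at regularly spaced sites so every short window carries
    its share of the divergence.

    Real inter-species divergence is spread along homologous regions
    (and includes indels an ungapped mapper cannot cross), so a 20%
    diverged target loses essentially all 23-29 nt piRNA windows at a
    3-mismatch budget; iid substitution would instead leave a lucky
    minority of windows mappable.
    """
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    step = max(1, int(round(1.0 / rate)))
    pos = np.arange(int(rng.integers(0, step)), arr.size, step)
    shifts = rng.integers(1, 4, size=pos.size)
    codes = np.searchsorted(BASES, arr[pos])
    arr[pos] = BASES[(codes + shifts) % 4]
    return "".join(arr)


# --- species pair --------------------------------------------------------


@dataclass(frozen=True)
class SpeciesPair:
    """Orthologous gene pairs for two diverged species.

    ``genes`` holds (mel_id, sim_id, mel_seq, sim_seq) tuples; paired
    sequences have equal length (substitutions only).
    """

    genes: list[tuple[str, str, str, str]]
    divergence: float
    seed: int

    def mel_records(self) -> list[tuple[str, str]]:
        return [(m, sm) for m, _, sm, _ in self.genes]

    def sim_records(self) -> list[tuple[str, str]]:
        return [(s, ss) for _, s, _, ss in self.genes]


def generate_species_pair(
    n_genes: int, gene_length: int, divergence: float, seed: int
) -> SpeciesPair:
    """Generate ``n_genes`` ortholog pairs at the given per-site
    substitution probability (0 <= divergence <= 0.25)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0.0 <= divergence <= 0.25):
        raise ValueError(f"divergence {divergence} outside [0, 0.25]")
    rng = np.random.default_rng(seed)
    genes = []
    width = len(str(n_genes))
    for i in range(n_genes):
        mel_seq = _random_dna(rng, gene_length)
        sim_seq = _mutate(rng, mel_seq, divergence)
        genes.append(
            (f"gene_mel_{i:0{width}d}", f"gene_sim_{i:0{width}d}", mel_seq, sim_seq)
        )
    return SpeciesPair(genes, divergence, seed)


# --- small RNA library ---------------------------------------------------


@dataclass(frozen=True)
class TEFamily:
    name: str
    te_class: str  # LTR | LINE | DNA
    consensus: str

    def __post_init__(self) -> None:
        if self.te_class not in ("LTR", "LINE", "DNA"):
            raise ValueError(f"unknown TE class {self.te_class!r}")


def make_te_panel(
    n_families: int = 5, consensus_length: int = 2000, seed: int = 0
) -> list[TEFamily]:
    """Random TE consensus panel cycling through LTR/LINE/DNA classes."""
    rng = np.random.default_rng(seed)
    classes = ("LTR", "LINE", "DNA")
    return [
        TEFamily(
            f"TE{i:02d}_{classes[i % 3]}",
            classes[i % 3],
            _random_dna(rng, consensus_length),
        )
        for i in range(n_families)
    ]


@dataclass
class PiRNAScenario:
    """Conditions for one simulated small-RNA library.

    ``pingpong_fraction`` and ``sense_antisense_ratio`` may be a single
    number (applied to every family) or a per-family mapping.
    ``sense_antisense_ratio`` is sense:antisense.
    """

    te_panel: Sequence[TEFamily]
    pingpong_fraction: float | Mapping[str, float] = 0.5
    sense_antisense_ratio: float | Mapping[str, float] = 1.0
    contaminant_fraction: float = 0.1
    library_size: int = 10_000
    read_length_range: tuple[int, int] = (23, 29)
    seed: int = 0
    adapter: str | None = DEFAULT_ADAPTER
    family_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.te_panel:
            raise ValueError("te_panel must be non-empty")
        names = [f.name for f in self.te_panel]
        if len(set(names)) != len(names):
            raise ValueError("TE family names must be unique")
        lo, hi = self.read_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid read_length_range")
        for fam in self.te_panel:
            if len(fam.consensus) < 3 * hi:
                raise ValueError(
                    f"consensus of {fam.name} shorter than 3x max read length"
                )
        for name in names:
            for frac in (self.pp_fraction(name), self.contaminant_fraction):
                if not (0.0 <= frac <= 1.0):
                    raise ValueError("fractions must lie in [0, 1]")
            if self.sa_ratio(name) <= 0:
                raise ValueError("sense_antisense_ratio must be positive")

    def pp_fraction(self, family: str) -> float:
        if isinstance(self.pingpong_fraction, Mapping):
            return float(self.pingpong_fraction[family])
        return float(self.pingpong_fraction)

    def sa_ratio(self, family: str) -> float:
        if isinstance(self.sense_antisense_ratio, Mapping):
            return float(self.sense_antisense_ratio[family])
        return float(self.sense_antisense_ratio)


@dataclass
class SimulatedLibrary:
    """A simulated raw library plus everything needed to process it."""

    library: ReadLibrary
    ground_truth: pd.DataFrame  # read_id, origin, strand, start, length, pingpong, partner
    te_refs: list[tuple[str, str]]
    contaminant_refs: list[tuple[str, str]]
    mirna_refs: list[tuple[str, str]]
    scenario: PiRNAScenario


def _allocate(total: int, weights: Sequence[float]) -> list[int]:
    """Integer allocation of ``total`` by weight, exact by largest remainder."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base))
    for i in range(short):
        base[order[i]] += 1
    return base.tolist()


def simulate_small_rna_library(scenario: PiRNAScenario) -> SimulatedLibrary:
    """Simulate one raw small-RNA library under ``scenario``.

    Exactly ``library_size`` reads are produced: TE-derived sense and
    antisense reads (with the planted ping-pong pair fraction among the
    antisense reads), rRNA-like contaminant reads, and miRNA-like reads.
    If ``scenario.adapter`` is set, the adapter is appended to every raw
    read so the trimming stage is exercised.
    """
    rng = np.random.default_rng(scenario.seed)
    lo, hi = scenario.read_length_range

    # internal contaminant references, deterministic under the seed
    contaminant_refs = [
        (f"rRNA_like_{i}", _random_dna(rng, 1500)) for i in range(2)
    ]
    mirna_refs = [(f"miR_like_{i}", _random_dna(rng, 22)) for i in range(20)]

    n_contam = int(round(scenario.library_size * scenario.contaminant_fraction))
    n_te_total = scenario.library_size - n_contam
    fams = list(scenario.te_panel)
    weights = (
        [scenario.family_weights[f.name] for f in fams]
        if scenario.family_weights
        else [1.0] * len(fams)
    )
    per_family = _allocate(n_te_total, weights) if n_te_total else [0] * len(fams)

    rows: list[dict] = []
    inserts: list[str] = []

    def emit(insert: str, origin: str, strand: str, start: int, pingpong: bool,
             partner: int | None) -> int:
        idx = len(inserts)
        inserts.append(insert)
        rows.append(
            dict(
                read_id=f"read_{idx:06d}",
                origin=origin,
                strand=strand,
                start=start,
                length=len(insert),
                pingpong=pingpong,
                partner=f"read_{partner:06d}" if partner is not None else "",
            )
        )
        return idx

    for fam, n_f in zip(fams, per_family):
        if n_f == 0:
            continue
        L = len(fam.consensus)
        r = scenario.sa_ratio(fam.name)
        n_sense = int(round(n_f * r / (1.0 + r)))
        n_anti = n_f - n_sense
        f_pp = scenario.pp_fraction(fam.name)
        n_pp = min(int(round(n_anti * f_pp)), n_anti) if n_sense else 0

        # sense reads; 5' ends kept away from the edges so a ping-pong
        # partner always fits
        sense_idx: list[int] = []
        for _ in range(n_sense):
            ln = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(hi, L - 2 * hi))
            sense_idx.append(
                emit(fam.consensus[start : start + ln], fam.name, "+", start, False, None)
            )
        # ping-pong antisense partners: 5' end 10 nt into the partner span
        for _ in range(n_pp):
            partner = sense_idx[int(rng.integers(0, len(sense_idx)))]
            p = rows[partner]["start"]
            ln = int(rng.integers(lo, hi + 1))
            q = p + 9  # overlap o = q - p + 1 = 10
            start = q - ln + 1
            emit(
                revcomp(fam.consensus[start : start + ln]),
                fam.name, "-", start, True, partner,
            )
            rows[partner]["pingpong"] = True
        # background antisense
        for _ in range(n_anti - n_pp):
            ln = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(hi, L - 2 * hi))
            emit(revcomp(fam.consensus[start : start + ln]), fam.name, "-", start, False, None)

    # contaminants: rRNA-like substrings and miRNA-like exact copies
    n_rrna = n_contam // 2
    for i in range(n_contam):
        if i < n_rrna:
            ref_id, ref_seq = contaminant_refs[int(rng.integers(0, len(contaminant_refs)))]
            ln = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(ref_seq) - ln + 1))
            emit(ref_seq[start : start + ln], ref_id, "+", start, False, None)
        else:
            ref_id, ref_seq = mirna_refs[int(rng.integers(0, len(mirna_refs)))]
            emit(ref_seq, ref_id, "+", 0, False, None)

    order = rng.permutation(len(inserts))
    adapter = scenario.adapter or ""
    reads = [(rows[i]["read_id"], inserts[i] + adapter) for i in order]
    truth = pd.DataFrame([rows[i] for i in order]).set_index("read_id")
    library = ReadLibrary(reads)
    return SimulatedLibrary(
        library=library,
        ground_truth=truth,
        te_refs=[(f.name, f.consensus) for f in fams],
        contaminant_refs=contaminant_refs,
        mirna_refs=mirna_refs,
        scenario=scenario,
    )


# --- RNA-seq counts ------------------------------------------------------


@dataclass
class DosagePlan:
    """Planted per-gene dosage categories for the hybrid alleles.

    ``categories`` maps mel gene id -> category. ``effect_fold`` scales
    the deviating allele(s); the half-dose baseline itself is always
    0.5x the parental mean.
    """

    categories: dict[str, str]
    nb_mean: float = 200.0
    nb_dispersion: float = 0.05
    effect_fold: float = 4.0
    #: log2-SD of the per-gene baseline mean around nb_mean; gives the
    #: matrix a realistic expression dynamic range (0 = all genes equal)
    mean_log2_sd: float = 1.5

    def __post_init__(self) -> None:
        for cat in self.categories.values():
            if cat not in DOSAGE_CATEGORIES:
                raise ValueError(f"unknown dosage category {cat!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.effect_fold < 2:
            raise ValueError("effect_fold must be >= 2")

    @classmethod
    def from_proportions(
        cls,
        gene_ids: Sequence[str],
        proportions: Mapping[str, float],
        seed: int,
        **kwargs,
    ) -> "DosagePlan":
        """Assign categories to genes with exact counts by largest
        remainder, in a seeded random order."""
        cats = list(proportions)
        counts = _allocate(len(gene_ids), [proportions[c] for c in cats])
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(list(gene_ids)))
        assignment: dict[str, str] = {}
        pos = 0
        for cat, n in zip(cats, counts):
            for g in shuffled[pos : pos + n]:
                assignment[g] = cat
            pos += n
        return cls(assignment, **kwargs)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """NB draw parameterized by mean and dispersion (var = mu + disp*mu^2)."""
    if mean == 0:
        return np.zeros(size, dtype=np.int64)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


SAMPLE_GROUPS = ("mel_parent", "sim_parent", "hybrid_mel_allele", "hybrid_sim_allele")


def simulate_rnaseq_counts(
    pair: SpeciesPair,
    plan: DosagePlan,
    n_replicates: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate an allele-resolved count matrix.

    Returns ``(counts, over_allele)``: counts indexed by mel gene id with
    MultiIndex columns (group, replicate) over the four sample groups,
    and a per-gene record of which allele carries the planted deviation
    for asymmetric categories (``mel``/``sim``/``""``).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (the study design minimum)")
    rng = np.random.default_rng(seed)
    gene_ids = [g[0] for g in pair.genes]
    missing = set(plan.categories) - set(gene_ids)
    if missing:
        raise ValueError(f"plan covers unknown genes: {sorted(missing)[:3]}")

    cols = pd.MultiIndex.from_product(
        [SAMPLE_GROUPS, range(1, n_replicates + 1)], names=["group", "replicate"]
    )
    data = np.zeros((len(gene_ids), len(cols)), dtype=np.int64)
    over_allele = {}
    for gi, gene in enumerate(gene_ids):
        base = plan.nb_mean * float(2.0 ** rng.normal(0.0, plan.mean_log2_sd))
        half = 0.5 * base
        cat = plan.categories.get(gene, "expected")
        mel_mult, sim_mult, which = 1.0, 1.0, ""
        if cat == "one_allele_over":
            which = "mel" if rng.random() < 0.5 else "sim"
            if which == "mel":
                mel_mult = plan.effect_fold
            else:
                sim_mult = plan.effect_fold
        elif cat == "both_over":
            mel_mult = sim_mult = plan.effect_fold
        elif cat == "both_under":
            mel_mult = sim_mult = 1.0 / plan.effect_fold
        elif cat == "mixed_other":
            which = "mel" if rng.random() < 0.5 else "sim"
            if which == "mel":
                mel_mult, sim_mult = plan.effect_fold, 1.0 / plan.effect_fold
            else:
                mel_mult, sim_mult = 1.0 / plan.effect_fold, plan.effect_fold
        over_allele[gene] = which
        means = {
            "mel_parent": base,
            "sim_parent": base,
            "hybrid_mel_allele": half * mel_mult,
            "hybrid_sim_allele": half * sim_mult,
        }
        row = []
        for grp in SAMPLE_GROUPS:
            row.append(_nb_draw(rng, means[grp], plan.nb_dispersion, n_replicates))
        data[gi] = np.concatenate(row)
    counts = pd.DataFrame(data, index=gene_ids, columns=cols)
    return counts, pd.Series(over_allele, name="over_allele")


# --- homology hits -------------------------------------------------------


def simulate_homology_hits(
    pair: SpeciesPair,
    transcripts_per_gene: int = 2,
    paralog_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[list[HomologyHit], dict[str, str], dict[str, str]]:
    """Simulate best-hit homology search results for ortholog resolution.

    Each mel gene gets ``transcripts_per_gene`` transcripts whose top
    hit is the true sim ortholog (bitscore from actual sequence
    identity) plus a weaker decoy hit. A ``paralog_fraction`` of genes
    has one transcript best-hitting a wrong gene, which downstream
    resolution must reject as a conflict.

    Returns (hits, tx2gene_mel, tx2gene_sim).
    """
    rng = np.random.default_rng(seed)
    hits: list[HomologyHit] = []
    tx2gene_mel: dict[str, str] = {}
    tx2gene_sim: dict[str, str] = {}
    n = len(pair.genes)
    for gi, (gm, gs, seq_m, seq_s) in enumerate(pair.genes):
        tx2gene_sim[f"{gs}_t1"] = gs
        conflicted = rng.random() < paralog_fraction and n > 1
        bad_tx = int(rng.integers(0, transcripts_per_gene)) if conflicted else -1
        for t in range(transcripts_per_gene):
            tx = f"{gm}_t{t + 1}"
            tx2gene_mel[tx] = gm
            ident = float(np.mean([a == b for a, b in zip(seq_m, seq_s)]))
            true_score = 2.0 * ident * len(seq_m)
            decoy_gi = int(rng.integers(0, n))
            if decoy_gi == gi:
                decoy_gi = (gi + 1) % n
            decoy_gene = pair.genes[decoy_gi][1]
            decoy_score = true_score * float(rng.uniform(0.3, 0.7))
            if t == bad_tx:
                # paralog confusion: the wrong gene wins for this transcript
                true_score, decoy_score = decoy_score, true_score * 1.1
            for subj, score in ((gs, true_score), (f"{decoy_gene}_t1", decoy_score)):
                subj_gene = gs if subj == gs else decoy_gene
                hits.append(
                    HomologyHit(
                        query_id=tx,
                        subject_id=f"{subj_gene}_t1",
                        pct_identity=round(100 * ident, 2),
                        aln_length=len(seq_m),
                        mismatches=int((1 - ident) * len(seq_m)),
                        gap_opens=0,
                        qstart=1,
                        qend=len(seq_m),
                        sstart=1,
                        send=len(seq_m),
                        evalue=1e-50,
                        bitscore=round(score if subj == gs else score, 1),
                    )
                )
    return hits, tx2gene_mel, tx2gene_sim


# --- cluster scenario ----------------------------------------------------


@dataclass
class ClusterScenario:
    """Merged two-genome segments with planted cluster-derived reads."""

    references: list[tuple[str, str]]  # merged mel+sim segments
    intervals: list[ClusterInterval]
    libraries: dict[str, ReadLibrary]  # genotype -> raw library
    truth: pd.DataFrame  # genotype, read_id, cluster, strand


def _complete_library(reads: list[tuple[str, str]]) -> ReadLibrary:
    """A library with every cascade stage recorded at full depth (reads
    generated post-processing, so all stages are pass-through)."""
    lib = ReadLibrary(list(reads))
    for stage in STAGES[1:]:
        lib.record_stage(stage)
    return lib


def simulate_cluster_scenario(
    seed: int = 0,
    segment_length: int = 12_000,
    divergence: float = 0.10,
    cluster_specs: Sequence[tuple[str, int, int, str]] = (
        ("42AB_like", 1000, 4000, "dual"),
        ("20A_like", 5000, 7000, "uni"),
        ("38C_like", 8000, 10_500, "dual"),
    ),
    reads_per_cluster: int = 600,
    hybrid_rate: float = 0.5,
    antisense_fraction_dual: float = 0.5,
    shared_fraction: float = 0.05,
    library_size: int = 4000,
    read_length_range: tuple[int, int] = (23, 29),
) -> ClusterScenario:
    """Simulate piRNA-cluster activity on a merged two-genome reference.

    The mel segment carries the cluster intervals; the sim segment is a
    diverged copy except for a small conserved stretch from which
    ``shared_fraction`` of reads are drawn - those occur verbatim in
    both genomes and must be discarded by unique mapping. The hybrid
    genotype emits ``hybrid_rate`` times the parental read count per
    cluster (0.5 = the heterozygous expectation). Every library is
    padded with background reads from inter-cluster regions up to
    ``library_size``, so the rpm denominator is genotype-independent
    as in a real library whose depth is dominated by non-cluster RNAs.
    """
    rng = np.random.default_rng(seed)
    mel = _random_dna(rng, segment_length)
    sim = _mutate(rng, mel, divergence)
    # conserved stretch, identical in both genomes, outside the clusters
    cons_start = segment_length - 600
    sim = sim[:cons_start] + mel[cons_start:]
    references = [("chr_mel", mel), ("chr_sim", sim)]
    intervals = [
        ClusterInterval("mel", "chr_mel", start, end, name, ctype)
        for name, start, end, ctype in cluster_specs
    ]
    lo, hi = read_length_range

    rates = {"mel": 1.0, "hybrid": hybrid_rate}
    libraries: dict[str, ReadLibrary] = {}
    truth_rows: list[dict] = []
    for genotype, rate in rates.items():
        reads: list[tuple[str, str]] = []
        for iv in intervals:
            n = int(round(reads_per_cluster * rate))
            anti_frac = antisense_fraction_dual if iv.cluster_type == "dual" else 0.0
            n_shared = int(round(n * shared_fraction))
            for j in range(n):
                ln = int(rng.integers(lo, hi + 1))
                if j < n_shared:
                    start = int(rng.integers(cons_start, segment_length - ln + 1))
                    origin = "shared"
                else:
                    start = int(rng.integers(iv.start, iv.end - ln + 1))
                    origin = iv.name
                strand = "-" if rng.random() < anti_frac else "+"
                seq = mel[start : start + ln]
                if strand == "-":
                    seq = revcomp(seq)
                rid = f"{genotype}_{iv.name}_{j:05d}"
                reads.append((rid, seq))
                truth_rows.append(
                    dict(genotype=genotype, read_id=rid, cluster=origin,
                         strand=strand, start=start)
                )
        # background padding from inter-cluster gaps keeps the library
        # depth (hence the rpm denominator) identical across genotypes
        gaps = []
        prev = 0
        for iv in sorted(intervals, key=lambda v: v.start):
            if iv.start - prev > 2 * hi:
                gaps.append((prev, iv.start))
            prev = iv.end
        if cons_start - prev > 2 * hi:
            gaps.append((prev, cons_start))
        for j in range(max(0, library_size - len(reads))):
            ln = int(rng.integers(lo, hi + 1))
            g0, g1 = gaps[int(rng.integers(0, len(gaps)))]
            start = int(rng.integers(g0, g1 - ln + 1))
            seq = mel[start : start + ln]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append((f"{genotype}_bg_{j:05d}", seq))
        libraries[genotype] = _complete_library(reads)
    return ClusterScenario(
        references, intervals, libraries, pd.DataFrame(truth_rows)
    )


# --- AT-chX / vasa scenario ----------------------------------------------


@dataclass
class AtChXScenario:
    """An X-linked repeat consensus targeting one species' allele.

    ``consensus`` is the repeat consensus; each allele transcript embeds
    a homologous region at a known offset and identity (high for the
    sim-like allele, low for the mel-like allele). ``cluster_reads`` are
    consensus-derived (mostly antisense to the target); ``allele_reads``
    are sense reads generated from each allele's own sequence within the
    region, ping-pong-paired with cluster reads in consensus coordinates.
    """

    consensus: tuple[str, str]
    alleles: dict[str, tuple[str, str]]  # label -> (transcript_id, seq)
    region_offset: dict[str, int]  # label -> offset of region in transcript
    identity: dict[str, float]
    cluster_reads: list[tuple[str, str]]
    allele_reads: dict[str, list[tuple[str, str]]]
    library: ReadLibrary  # pooled library for normalization


def simulate_atchx_scenario(
    seed: int = 0,
    consensus_length: int = 800,
    flank: int = 400,
    identities: Mapping[str, float] = None,
    n_pairs: int = 300,
    n_background: int = 200,
    read_length_range: tuple[int, int] = (23, 29),
) -> AtChXScenario:
    """Simulate repeat-cluster piRNAs targeting species-specific alleles.

    Defaults plant 95% identity for the sim-like allele (pairs survive a
    3-mismatch mapping gate) and 80% for the mel-like allele (pairs are
    lost), mirroring the asymmetric targeting of the two alleles.
    """
    if identities is None:
        identities = {"sim": 0.95, "mel": 0.80}
    rng = np.random.default_rng(seed)
    lo, hi = read_length_range
    consensus = _random_dna(rng, consensus_length)

    alleles: dict[str, tuple[str, str]] = {}
    offsets: dict[str, int] = {}
    for label, ident in identities.items():
        region = _mutate_evenly(rng, consensus, 1.0 - ident)
        left = _random_dna(rng, flank)
        right = _random_dna(rng, flank)
        alleles[label] = (f"vasa_{label}", left + region + right)
        offsets[label] = flank

    cluster_reads: list[tuple[str, str]] = []
    allele_reads: dict[str, list[tuple[str, str]]] = {k: [] for k in identities}
    # ping-pong pairs: sense read from the allele region, antisense
    # partner from the consensus, 5' ends 10 nt apart in consensus coords
    for label in identities:
        _, tx = alleles[label]
        off = offsets[label]
        for j in range(n_pairs):
            p = int(rng.integers(hi, consensus_length - 2 * hi))
            ln_s = int(rng.integers(lo, hi + 1))
            allele_reads[label].append(
                (f"{label}_sense_{j:05d}", tx[off + p : off + p + ln_s])
            )
            ln_a = int(rng.integers(lo, hi + 1))
            q = p + 9
            start = q - ln_a + 1
            cluster_reads.append(
                (
                    f"atchx_{label}_{j:05d}",
                    revcomp(consensus[start : start + ln_a]),
                )
            )
    for j in range(n_background):
        ln = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, consensus_length - ln + 1))
        strand = "-" if rng.random() < 0.5 else "+"
        seq = consensus[start : start + ln]
        cluster_reads.append(
            (f"atchx_bg_{j:05d}", revcomp(seq) if strand == "-" else seq)
        )

    pooled = cluster_reads + [r for rs in allele_reads.values() for r in rs]
    return AtChXScenario(
        consensus=("AT_chX_consensus", consensus),
        alleles=alleles,
        region_offset=offsets,
        identity=dict(identities),
        cluster_reads=cluster_reads,
        allele_reads=allele_reads,
        library=_complete_library(pooled),
    )
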