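# Methods

This note documents the models, conventions and deliberate choices
behind each layer of the package, what the synthetic generators do and
do not emulate, and the known limitations.

## Coordinates and formats

All internal coordinates are 0-based half-open. SAM (1-based) and
12-column blast tabular (1-based inclusive) are converted at the I/O
boundary and nowhere else. Only the SAM fields the pipeline consumes
are modelled (QNAME, FLAG strand/unmapped bits, RNAME, POS, SEQ, NM);
gapped CIGARs are rejected because the mapper is ungapped; a record
without an NM tag is kept with its mismatch count flagged unknown.
Readers reject malformed input (duplicate FASTA ids, non-DNA
characters, degenerate BED intervals, wrong blast-tab column counts)
rather than coercing it.

## Small-RNA cascade and normalization

Stages: raw → adapter_trimmed → quality_kept → contaminant_filtered →
mirna_filtered → length_selected, with the surviving read count
recorded at each stage (depths are checked to be non-increasing).

- Adapter trimming removes the longest read suffix exactly matching a
  prefix of the adapter (≥ 3 nt overlap). No error tolerance: the
  synthetic reads are generated error-free, and tolerance would be a
  calibration knob rather than a different algorithm.
- Quality filtering applies only to FASTQ input (mean phred > 30);
  FASTA inputs pass through.
- Contaminant and miRNA filtering remove reads aligning anywhere in
  the respective reference set, either strand, ungapped, ≤ 3
  mismatches.
- Length selection keeps 23–29 nt inclusive on both ends (the
  field's naming convention for the piRNA-sized fraction).

**rpm denominator.** rpm = count / normalization_depth × 10⁶ with the
depth pinned to the post-contaminant, pre-miRNA stage: miRNAs are
genuine cellular small RNAs and belong in the sequencing-depth
denominator even though they are excluded from the piRNA fraction.
Whether the denominator should instead precede rRNA/tRNA filtering is
genuinely ambiguous; `norm_stage` overrides the default (e.g. `"raw"`).

## Mapper

Ungapped Hamming-distance mapping replaces seed-heuristic aligners: at
23–29 nt and ≤ 3 mismatches the exact search is feasible and fully
specified, where seed heuristics ("mismatches in the first L bases
only") are not. The implementation uses a pigeonhole k-mer index
(k = ⌊min read length / (max_mm + 1)⌋, ≥ 4): a read within the
mismatch budget must match one of max_mm + 1 disjoint seeds exactly,
so seed lookups enumerate all candidate placements, which are then
verified base-by-base with numpy. `map_reads_exhaustive` is a separate
plain window scan kept as the reference path; the test suite asserts
exact agreement between the two on random instances at 0–3 mismatches.

Policies: `all_hits` returns every placement; `one_best` takes the
minimum-mismatch placement with the deterministic tie-break
(lexicographic reference id, then start, then `+` before `-`);
`best_unique` discards a read entirely when its minimum-mismatch
placement is not unique — on a merged two-genome reference this is
simultaneously the uniqueness and the species-specificity rule. `N`
bases mismatch everything, including other `N`s (conservative).
Identical read sequences are collapsed before mapping and re-expanded,
so duplicated reads keep their abundance downstream.

## Ping-pong statistic

Overlap between a sense read (5′ end at p = start) and an antisense
read (5′ end at q = start + length − 1) is o = q − p + 1; a perfect
ping-pong pair gives o = 10. Pair counting is exhaustive over read
pairs with abundance weighting; mismatch counts of the contributing
alignments do not weight pairs. z₁₀ standardizes bin 10 against the
other 29 bins with the sample SD; whether the background should include
bin 10 is not settled usage, so it is a flag
(`include_focal_in_background`, default off — including it only shrinks
the score). Degenerate histograms return an undefined, flagged score
instead of raising: an all-zero histogram, or a zero background SD with
an off-mean bin 10; a flat histogram scores exactly 0. The cross-set
variant counts only pairs with one member from each of two alignment
sets (either strand arrangement) and is symmetric in its arguments.

## TE quantification and silencing potential

Silencing potential per genotype is antisense rpm > 100, strict at the
boundary. Fold reduction is parent/hybrid antisense rpm. The fivefold
cohort rule is applied to **unrounded** ratios with an inclusive ≥ 5
boundary, while reported folds are rounded half-up to one decimal: on
the bundled seven-family table the *blood* family sits at 5.04-fold vs
the *D. simulans* parent, and only the inclusive-on-raw-ratios reading
reproduces the published cohort counts (3 families reduced vs both
parents, 6 vs at least one). A hybrid rpm of exactly 0 makes the ratio
undefined; for cohort membership it counts as reduced when the parent
rpm is positive.

## Differential expression

The packaged shrinkage estimators used in practice are deliberately
replaced by a transparent stand-in: the contribution this layer serves
is the decision thresholds and downstream classification, not the
fitter. Per feature, counts are normalized by median-of-ratios size
factors; the NB dispersion α (var = μ + αμ²) is estimated by moments,
pooled across the two groups, floored at 0; the Wald statistic is
log₂FC / SE with the delta-method SE. The statistic is referred to a
Student t with n_A + n_B − 2 df rather than a normal: at two to three
replicates per group (the relevant study design) the normal reference
roughly doubles the nominal type-I error, while the t reference keeps
it at the nominal level across the dispersions and means the test
suite probes. The cost is power near the decision boundary: an effect
exactly at fivefold can never be detected in ≥ 90% of features by an
unbiased estimator under a strict > log₂5 rule (half the estimates fall
below the true value), so the power test plants 8-fold effects in a
10% minority at 4 replicates, where detection exceeds 90% with intact
calibration. When either group mean is zero, a 0.5 pseudocount enters
the fold change and the feature is flagged; all-zero features get
p = 1 and log₂FC = 0. No dispersion shrinkage, independent filtering
or outlier handling.

## Allele dosage

Ortholog resolution keeps, per query transcript, the top-bitscore hit
(ties break to the lexicographically smaller subject and flag the
pair); a gene pair is accepted only when all transcripts of the gene
agree on one subject gene; and a subject gene claimed by several query
genes is kept only for the claimant with the highest summed bitscore so
each gene occurs in at most one accepted pair.

The half-dose expectation (0.5 of the two-copy parental level) anchors
classification. The band is a declared choice — the thresholds behind
published category percentages are not stated anywhere — set to
band_log2 = 1.0 (within twofold of the half dose), consistent with the
twofold gene-level DE convention, and exposed as a parameter. Ratios
are computed on depth-normalized replicate means with a 0.5
pseudocount; hybrid allele columns share one library, so their size
factors come from the summed whole-hybrid sample. Classification is by
the pair of per-allele calls; all five categories are symmetric under
swapping species labels.

For the repeat-cluster/allele cross signature, both read populations
are mapped onto the allele transcript itself (one-best, ≤ 3
mismatches): divergence between the repeat consensus and an allele
beyond the mismatch budget empties the cluster-mapped set, which is
exactly the species-specificity readout.

## Cluster activity

Unique zero-mismatch mapping on the merged two-genome reference; a read
is assigned to an interval when its 5′ end lies inside it (a single
unambiguous rule for boundary reads; full containment is a flag).
Sense/antisense is relative to the + strand of the interval's
reference. The hybrid/parent ratio is compared to the expected
heterozygous level of 0.5.

## Synthetic generators: what they emulate, and what not

All generators draw from a single `numpy` PCG64 stream per call, are
bit-reproducible per seed, and emit ground truth (read origin, strand,
ping-pong pairing and partner, planted dosage category).

- Orthologs diverge by substitutions only, so paired coordinates align
  1:1 and allele-specific mapping is unambiguous; defaults: 5%
  divergence, 200–500 genes of a few hundred nt.
- Small-RNA libraries: read lengths 23–29 nt; TE consensus panels of
  ~2 kb random sequence; contaminant fraction 0.1 split between
  rRNA-like substring reads and miRNA-like exact copies; a standard
  small-RNA 3′ adapter appended to raw reads; library sizes 50,000 for
  single-library signal checks and 3,000–10,000 for multi-seed sweeps
  (desk-scale sizes chosen so whole-suite runs stay interactive).
  Ping-pong pairs are built by construction — the antisense 5′ end is
  placed 10 nt into a sense partner's span — because the statistic
  depends only on 5′–5′ geometry, not slicing kinetics. piRNA 5′ ends
  are uniform along the consensus; real piRNA position distributions
  are strongly non-uniform, and nothing here validates behavior under
  that non-uniformity.
- RNA-seq counts: NB with mean 200, dispersion 0.05, per-gene baseline
  means log-normal (log2 SD 1.5) to give a realistic dynamic range;
  hybrid alleles at 0.5× the baseline scaled by the planted category
  effect (fold ≥ 2, default 4). Two replicates minimum (the study
  design floor); recovery tests use 3.
- The repeat-targeting scenario plants allele/consensus identities of
  95% and 80% with substitutions at regular spacing, so every
  piRNA-sized window carries its share of the divergence. Real
  divergence additionally contains indels, which an ungapped mapper
  cannot cross; regular spacing reproduces that all-windows-blocked
  behavior where iid substitutions would leave a lucky minority of
  windows mappable and blur the allele asymmetry.
- Cluster scenarios use ~12 kb genome segments (desk-scale stand-ins
  for genomes, declared openly), 10% inter-genome divergence, a small
  conserved stretch to exercise the uniqueness rule, and libraries
  padded with inter-cluster background reads to a fixed size so the rpm
  denominator is genotype-independent, as in real libraries whose depth
  is dominated by non-cluster RNAs.

Passing on these generators shows the statistics and classification
rules behave as specified under their own assumptions; it does not
validate behavior under sequencing error, ligation bias, non-uniform
piRNA production, indel divergence, or genome-scale repeat structure.

## Numerical conventions

Rounding of reported fold values is decimal half-up (not banker's).
Ties in mapping break lexicographically, never randomly. Undefined
quantities (zero denominators, empty histograms, zero-variance
correlations) return flagged None/NaN rather than raising, except where
an input is malformed, which raises. BH adjustment delegates to
statsmodels; the test suite checks it against a hand-rolled step-up.

## Known limitations

No BAM/CRAM or quality-aware processing; no UMI handling; no indels or
spliced alignment; no 1U/10A nucleotide-bias or phasing statistics; no
GO enrichment. The mapper is not built for genome-scale references —
its contract is exactness at desk scale, checked against the window
scan.
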