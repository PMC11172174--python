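import numpy as np
import pandas as pd
import pytest

from hspirna import alleles
from hspirna.alleles import (
    classify_dosage,
    expression_correlation,
    resolve_orthologs,
    vasa_atchx_report,
)
from hspirna.io import HomologyHit
from hspirna.simulate import (
    DosagePlan,
    generate_species_pair,
    simulate_atchx_scenario,
    simulate_homology_hits,
    simulate_rnaseq_counts,
)


def _hit(q, s, score):
    return HomologyHit(q, s, 95.0, 100, 5, 0, 1, 100, 1, 100, 1e-30, score)


class TestResolveOrthologs:
    MAPS = (
        {"a1": "A", "a2": "A"},
        {"X_t1": "X", "Y_t1": "Y"},
    )

    def test_agreeing_transcripts_accepted(self):
        hits = [_hit("a1", "X_t1", 500), _hit("a2", "X_t1", 450),
                _hit("a1", "Y_t1", 100)]
        (pair,) = resolve_orthologs(hits, *self.MAPS)
        assert pair.accepted and pair.support == 2
        assert (pair.gene_mel, pair.gene_sim) == ("A", "X")

    def test_disagreeing_transcripts_conflict(self):
        hits = [_hit("a1", "X_t1", 500), _hit("a2", "Y_t1", 450)]
        (pair,) = resolve_orthologs(hits, *self.MAPS)
        assert pair.conflict and not pair.accepted

    def test_bitscore_tie_breaks_lexicographically_and_flags(self):
        hits = [_hit("a1", "Y_t1", 500), _hit("a1", "X_t1", 500),
                _hit("a2", "X_t1", 400)]
        (pair,) = resolve_orthologs(hits, *self.MAPS)
        assert pair.gene_sim == "X"  # lexicographically smaller subject wins
        assert pair.conflict

    def test_unknown_transcript_named_in_error(self):
        with pytest.raises(KeyError, match="zz"):
            resolve_orthologs([_hit("zz", "X_t1", 10)], *self.MAPS)

    def test_synthetic_acceptance_rate_at_low_divergence(self):
        """Most genes resolve to orthologs when divergence is <= 0.1."""
        pair = generate_species_pair(200, 400, 0.1, 31)
        hits, m2g, s2g = simulate_homology_hits(pair, seed=32)
        pairs = resolve_orthologs(hits, m2g, s2g)
        accepted = [p for p in pairs if p.accepted]
        assert len(accepted) / len(pairs) >= 0.9
        # accepted pairings are the planted ones
        assert all(
            p.gene_sim == p.gene_mel.replace("mel", "sim") for p in accepted
        )


class TestClassifyDosage:
    @pytest.mark.parametrize(
        "rm,rs,category",
        [
            (0.5, 0.5, "expected"),
            (2.0, 0.5, "one_allele_over"),
            (0.5, 2.0, "one_allele_over"),
            (2.5, 2.5, "both_over"),
            (0.1, 0.1, "both_under"),
            (2.5, 0.1, "mixed_other"),
        ],
    )
    def test_category_mapping(self, rm, rs, category):
        assert classify_dosage(rm, rs) == category

    def test_species_label_swap_symmetry(self, rng):
        for _ in range(50):
            rm, rs = rng.uniform(0.01, 4, size=2)
            a, b = classify_dosage(rm, rs), classify_dosage(rs, rm)
            assert a == b  # all categories are symmetric in the two alleles

    def test_band_edges(self):
        # band_log2=1 around the half-dose: over iff ratio > 1, under iff < 0.25
        assert classify_dosage(1.0001, 0.5) == "one_allele_over"
        assert classify_dosage(0.9999, 0.5) == "expected"
        assert classify_dosage(0.2499, 0.2499) == "both_under"


class TestAlleleExpression:
    def _counts(self, parent, hyb_mel, hyb_sim, n_genes=4):
        cols = pd.MultiIndex.from_product(
            [
                ["mel_parent", "sim_parent", "hybrid_mel_allele", "hybrid_sim_allele"],
                [1, 2],
            ],
            names=["group", "replicate"],
        )
        row = [parent] * 4 + [hyb_mel] * 2 + [hyb_sim] * 2
        return pd.DataFrame(
            [row] * n_genes, index=[f"g{i}" for i in range(n_genes)], columns=cols
        )

    def test_half_dose_ratios(self):
        tab = alleles.allele_expression(self._counts(1000, 500, 500))
        assert tab["ratio_mel"].iloc[0] == pytest.approx(0.5, rel=1e-3)
        assert tab["ratio_sim"].iloc[0] == pytest.approx(0.5, rel=1e-3)
        assert (tab["category"] == "expected").all()

    def test_planted_half_dose_distribution_mode(self):
        pair = generate_species_pair(300, 200, 0.05, 41)
        plan = DosagePlan({g[0]: "expected" for g in pair.genes})
        counts, _ = simulate_rnaseq_counts(pair, plan, 3, seed=42)
        tab = alleles.allele_expression(counts)
        med = np.median(np.concatenate([tab["ratio_mel"], tab["ratio_sim"]]))
        assert abs(med - 0.5) <= 0.1

    def test_category_recovery_within_5_points(self):
        """Planted dosage proportions are recovered within +/-5 points."""
        props = {
            "expected": 0.60,
            "one_allele_over": 0.15,
            "both_over": 0.10,
            "both_under": 0.05,
            "mixed_other": 0.10,
        }
        pair = generate_species_pair(500, 200, 0.05, 21)
        plan = DosagePlan.from_proportions(
            [g[0] for g in pair.genes], props, seed=5, effect_fold=4.0
        )
        counts, _ = simulate_rnaseq_counts(pair, plan, 3, seed=6)
        freq = alleles.category_frequencies(alleles.allele_expression(counts))
        for cat, p in props.items():
            assert abs(freq.get(cat, 0.0) - p) <= 0.05


class TestExpressionCorrelation:
    def test_perfect_correlation(self, rng):
        x = rng.uniform(1, 1000, size=50)
        assert expression_correlation(x, x) == pytest.approx(1.0)

    def test_perfect_anticorrelation_on_log_scale(self, rng):
        logx = rng.uniform(0, 10, size=50)
        x = 2.0**logx - 0.5
        y = 2.0**(-logx) - 0.5
        assert expression_correlation(x, y) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        assert expression_correlation([5, 5, 5], [1, 2, 3]) is None

    def test_simulated_half_dose_hybrid_correlates(self):
        """Across a realistic expression dynamic range, hybrid allele
        expression tracks the parental level (log-scale r >= 0.9)."""
        pair = generate_species_pair(400, 200, 0.05, 51)
        plan = DosagePlan(
            {g[0]: "expected" for g in pair.genes},
            nb_mean=300.0,
            nb_dispersion=0.05,
        )
        counts, _ = simulate_rnaseq_counts(pair, plan, 3, seed=52)
        hyb = counts["hybrid_mel_allele"].mean(axis=1)
        par = counts["mel_parent"].mean(axis=1)
        assert expression_correlation(hyb, par) >= 0.9


class TestVasaAtChXReport:
    def test_asymmetric_allele_targeting(self):
        """Cluster piRNAs pair with the high-identity allele (z10 >= 3)
        but the diverged allele fails the 3-mismatch gate."""
        ax = simulate_atchx_scenario(seed=9)
        rep = vasa_atchx_report(
            ax.cluster_reads, ax.allele_reads, ax.alleles, ax.consensus, ax.region_offset
        )
        sim_score = rep["sim"]["z10"]
        mel_score = rep["mel"]["z10"]
        assert sim_score.defined and sim_score.z10 >= 3
        assert (not mel_score.defined) or mel_score.z10 < 3
        assert rep["mel"]["n_cluster_alignments"] < rep["sim"]["n_cluster_alignments"]

    def test_no_cluster_reads_gives_empty_tracks(self):
        ax = simulate_atchx_scenario(seed=9, n_pairs=5, n_background=0)
        rep = vasa_atchx_report(
            [], {k: [] for k in ax.allele_reads}, ax.alleles, ax.consensus, ax.region_offset
        )
        for r in rep.values():
            assert not r["z10"].defined
            assert (r["coverage"][["sense", "antisense"]].to_numpy() == 0).all()

    def test_doubling_abundance_keeps_score_sign(self):
        ax = simulate_atchx_scenario(seed=9, n_pairs=50, n_background=30)
        rep1 = vasa_atchx_report(
            ax.cluster_reads, ax.allele_reads, ax.alleles, ax.consensus, ax.region_offset
        )
        w = {rid: 2.0 for rid, _ in ax.cluster_reads}
        w.update({rid: 2.0 for rs in ax.allele_reads.values() for rid, _ in rs})
        rep2 = vasa_atchx_report(
            ax.cluster_reads, ax.allele_reads, ax.alleles, ax.consensus,
            ax.region_offset, weights=w,
        )
        s1, s2 = rep1["sim"]["z10"], rep2["sim"]["z10"]
        assert s1.defined and s2.defined
        assert np.sign(s1.z10) == np.sign(s2.z10)
        assert s2.z10 >= 3

    def test_consensus_outside_transcript_rejected(self):
        ax = simulate_atchx_scenario(seed=9, n_pairs=5, n_background=0)
        bad_offsets = {k: 10**6 for k in ax.region_offset}
        with pytest.raises(ValueError, match="does not fit"):
            vasa_atchx_report(
                ax.cluster_reads, ax.allele_reads, ax.alleles, ax.consensus, bad_offsets
            )
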