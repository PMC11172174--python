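import numpy as np
import pytest

from hspirna import io
from hspirna.simulate import (
    DosagePlan,
    PiRNAScenario,
    SAMPLE_GROUPS,
    generate_species_pair,
    make_te_panel,
    simulate_cluster_scenario,
    simulate_rnaseq_counts,
    simulate_small_rna_library,
)


class TestSpeciesPair:
    def test_zero_divergence_gives_identical_orthologs(self):
        pair = generate_species_pair(10, 500, 0.0, 1)
        assert all(m == s for _, _, m, s in pair.genes)

    def test_divergence_within_binomial_bounds(self):
        pair = generate_species_pair(100, 1000, 0.05, 7)
        mismatches = sum(
            sum(a != b for a, b in zip(m, s)) for _, _, m, s in pair.genes
        )
        frac = mismatches / 100_000
        sigma = np.sqrt(0.05 * 0.95 / 100_000)
        assert abs(frac - 0.05) <= 3 * sigma

    def test_byte_identical_fasta_per_seed(self, tmp_path):
        for run in ("a", "b"):
            pair = generate_species_pair(20, 300, 0.08, 7)
            io.write_fasta(pair.mel_records(), tmp_path / f"{run}_mel.fa")
            io.write_fasta(pair.sim_records(), tmp_path / f"{run}_sim.fa")
        assert (tmp_path / "a_mel.fa").read_bytes() == (tmp_path / "b_mel.fa").read_bytes()
        assert (tmp_path / "a_sim.fa").read_bytes() == (tmp_path / "b_sim.fa").read_bytes()

    def test_divergence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_species_pair(5, 100, 0.3, 0)


class TestSmallRNALibrary:
    def test_read_count_conserved_exactly(self, te_panel):
        for size in (999, 5000):
            sc = PiRNAScenario(te_panel=te_panel, library_size=size, seed=2)
            sim = simulate_small_rna_library(sc)
            assert len(sim.library.reads) == size
            assert len(sim.ground_truth) == size

    def test_deterministic_per_seed(self, te_panel):
        a = simulate_small_rna_library(PiRNAScenario(te_panel=te_panel, seed=5, library_size=500))
        b = simulate_small_rna_library(PiRNAScenario(te_panel=te_panel, seed=5, library_size=500))
        assert a.library.reads == b.library.reads
        assert a.ground_truth.equals(b.ground_truth)

    def test_all_contaminant_library_empties_downstream(self, te_panel):
        from hspirna import smallrna

        sc = PiRNAScenario(
            te_panel=te_panel, contaminant_fraction=1.0, library_size=400, seed=3
        )
        sim = simulate_small_rna_library(sc)
        lib = smallrna.process_library(
            sim.library.reads,
            adapter=sc.adapter,
            contaminant_refs=sim.contaminant_refs,
            mirna_refs=sim.mirna_refs,
        )
        assert lib.reads == []

    def test_pingpong_pairs_have_10nt_5p_overlap(self, small_sim):
        truth = small_sim.ground_truth
        paired = truth[(truth["strand"] == "-") & truth["pingpong"]]
        for rid, row in paired.head(50).iterrows():
            partner = truth.loc[row["partner"]]
            q = row["start"] + row["length"] - 1
            assert q - partner["start"] + 1 == 10

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            PiRNAScenario(te_panel=[], seed=0)


class TestRNASeqCounts:
    def test_expected_category_gives_half_dose(self):
        pair = generate_species_pair(200, 100, 0.05, 11)
        plan = DosagePlan({g[0]: "expected" for g in pair.genes}, mean_log2_sd=0.0)
        counts, _ = simulate_rnaseq_counts(pair, plan, 3, seed=12)
        parent = counts["mel_parent"].to_numpy().mean()
        hybrid = counts["hybrid_mel_allele"].to_numpy().mean()
        se = counts["hybrid_mel_allele"].to_numpy().std() / np.sqrt(600)
        assert abs(hybrid - 0.5 * parent) <= 3 * se

    def test_both_under_scales_both_alleles_down(self):
        pair = generate_species_pair(200, 100, 0.05, 13)
        plan = DosagePlan(
            {g[0]: "both_under" for g in pair.genes}, effect_fold=4.0, mean_log2_sd=0.0
        )
        counts, _ = simulate_rnaseq_counts(pair, plan, 3, seed=14)
        parent = counts["mel_parent"].to_numpy().mean()
        for grp in ("hybrid_mel_allele", "hybrid_sim_allele"):
            hybrid = counts[grp].to_numpy().mean()
            se = counts[grp].to_numpy().std() / np.sqrt(600)
            assert abs(hybrid - 0.125 * parent) <= 3 * se

    def test_zero_mean_gives_all_zero_matrix(self):
        pair = generate_species_pair(10, 100, 0.0, 1)
        plan = DosagePlan({g[0]: "expected" for g in pair.genes}, nb_mean=0.0)
        counts, _ = simulate_rnaseq_counts(pair, plan, 2, seed=1)
        assert (counts.to_numpy() == 0).all()

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError):
            DosagePlan({"g": "expected"}, nb_dispersion=0.0)

    def test_single_replicate_rejected(self):
        pair = generate_species_pair(5, 100, 0.0, 1)
        plan = DosagePlan({g[0]: "expected" for g in pair.genes})
        with pytest.raises(ValueError):
            simulate_rnaseq_counts(pair, plan, 1, seed=0)

    def test_column_layout(self):
        pair = generate_species_pair(5, 100, 0.0, 1)
        plan = DosagePlan({g[0]: "expected" for g in pair.genes})
        counts, _ = simulate_rnaseq_counts(pair, plan, 2, seed=0)
        assert tuple(counts.columns.get_level_values("group").unique()) == SAMPLE_GROUPS

    def test_proportions_allocated_exactly(self):
        genes = [f"g{i}" for i in range(100)]
        props = {"expected": 0.6, "one_allele_over": 0.15, "both_over": 0.1,
                 "both_under": 0.05, "mixed_other": 0.1}
        plan = DosagePlan.from_proportions(genes, props, seed=1)
        from collections import Counter

        got = Counter(plan.categories.values())
        assert got == {"expected": 60, "one_allele_over": 15, "both_over": 10,
                       "both_under": 5, "mixed_other": 10}


def test_cluster_scenario_sense_antisense_recovered_within_3sd():
    cs = simulate_cluster_scenario(seed=8, antisense_fraction_dual=0.3)
    truth = cs.truth.query("genotype == 'mel' and cluster == '42AB_like'")
    n = len(truth)
    anti = (truth["strand"] == "-").sum()
    sigma = np.sqrt(n * 0.3 * 0.7)
    assert abs(anti - 0.3 * n) <= 3 * sigma
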