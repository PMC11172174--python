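import numpy as np
import pytest

from hspirna import smallrna
from hspirna.smallrna import ReadLibrary, rpm


def _brute_trim(seq, adapter, min_overlap):
    for i in range(len(seq) - min_overlap + 1):
        tail = seq[i:]
        if len(tail) <= len(adapter) and adapter.startswith(tail):
            return seq[:i]
    return seq


class TestTrimAdapter:
    def test_exact_suffix_removed(self):
        out = smallrna.trim_adapter([("r", "ACGTACGTAGATCGGAAG")], "AGATCGGAAG", 3)
        assert out == [("r", "ACGTACGT")]

    def test_read_without_adapter_unchanged(self):
        out = smallrna.trim_adapter([("r", "ACGTACGTACGT")], "AGATCGGAAG", 3)
        assert out == [("r", "ACGTACGTACGT")]

    def test_fully_adapter_read_dropped(self):
        assert smallrna.trim_adapter([("r", "AGATCGGAAG")], "AGATCGGAAG", 3) == []

    def test_matches_bruteforce_on_planted_adapters(self, rng):
        adapter = "AGATCGGAAGAGC"
        reads = []
        for i in range(500):
            insert = "".join(rng.choice(list("ACGT"), size=rng.integers(15, 35)))
            n_ad = int(rng.integers(0, len(adapter) + 1))
            reads.append((f"r{i}", insert + adapter[:n_ad]))
        got = dict(smallrna.trim_adapter(reads, adapter, 3))
        want = {
            rid: _brute_trim(seq, adapter, 3)
            for rid, seq in reads
            if _brute_trim(seq, adapter, 3)
        }
        assert got == want


def _window_scan(read, refs, max_mm):
    from hspirna.align import revcomp

    for _, ref in refs:
        for s in (read, revcomp(read)):
            for start in range(len(ref) - len(s) + 1):
                mm = sum(a != b for a, b in zip(ref[start : start + len(s)], s))
                if mm <= max_mm:
                    return True
    return False


class TestFilters:
    def test_exact_contaminant_substring_removed(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=300))
        lib = ReadLibrary([("r1", ref[50:75]), ("r2", "".join(rng.choice(list("ACGT"), size=25)))])
        out = smallrna.filter_contaminants(lib, [("rRNA", ref)], 3)
        assert [r[0] for r in out.reads] == ["r2"]

    def test_survivors_match_bruteforce_scan(self, rng):
        refs = [("c1", "".join(rng.choice(list("ACGT"), size=200)))]
        reads = []
        for i in range(200):
            if i % 3 == 0:  # planted near-contaminant with 0-4 errors
                start = int(rng.integers(0, 175))
                seq = list(refs[0][1][start : start + 25])
                for _ in range(int(rng.integers(0, 5))):
                    seq[int(rng.integers(0, 25))] = str(rng.choice(list("ACGT")))
                reads.append((f"r{i}", "".join(seq)))
            else:
                reads.append((f"r{i}", "".join(rng.choice(list("ACGT"), size=25))))
        out = smallrna.filter_contaminants(ReadLibrary(reads), refs, 3)
        expected = [r for r in reads if not _window_scan(r[1], refs, 3)]
        assert out.reads == expected

    def test_mirna_filter_keeps_normalization_depth(self, rng):
        mirna = "".join(rng.choice(list("ACGT"), size=22))
        reads = [(f"m{i}", mirna) for i in range(100)] + [
            (f"r{i}", "".join(rng.choice(list("ACGT"), size=25))) for i in range(900)
        ]
        lib = ReadLibrary(reads)
        lib = smallrna.filter_contaminants(lib, [("c", "T" * 100)], 3)
        lib = smallrna.filter_mirna(lib, [("mir", mirna)], 3)
        assert lib.stage_depths["contaminant_filtered"] == 1000
        assert lib.stage_depths["mirna_filtered"] == 900
        assert lib.normalization_depth == 1000  # depth before miRNA filtration

    def test_all_mirna_library_empties_but_depth_stays(self):
        mirna = "ACGTACGTACGTACGTACGTAC"
        lib = ReadLibrary([(f"m{i}", mirna) for i in range(10)])
        lib.record_stage("contaminant_filtered")
        out = smallrna.filter_mirna(lib, [("mir", mirna)], 0)
        assert out.reads == []
        assert out.normalization_depth == 10


class TestLengthSelection:
    @pytest.mark.parametrize(
        "length,kept", [(22, False), (23, True), (29, True), (30, False)]
    )
    def test_inclusive_23_29_bounds(self, length, kept):
        lib = smallrna.select_length(
            _lib_with_stages([("r", "A" * length)]), 23, 29
        )
        assert bool(lib.reads) is kept

    def test_empty_library_passes_through(self):
        assert smallrna.select_length(_lib_with_stages([]), 23, 29).reads == []

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            smallrna.select_length(_lib_with_stages([]), 29, 23)


def _lib_with_stages(reads):
    lib = ReadLibrary(reads)
    for st in ("adapter_trimmed", "quality_kept", "contaminant_filtered", "mirna_filtered"):
        lib.record_stage(st)
    return lib


class TestRpm:
    def test_basic_arithmetic(self):
        lib = ReadLibrary([("r", "A" * 25)] * 0)
        lib.stage_depths = {"raw": 10**6, "contaminant_filtered": 10**6}
        assert rpm(50, lib) == 50.0
        assert rpm(0, lib) == 0.0

    def test_hybrid_table_style_rounding(self):
        lib = ReadLibrary([])
        lib.stage_depths = {"raw": 999730, "contaminant_filtered": 999730}
        assert round(rpm(1112, lib), 1) == 1112.3

    def test_zero_depth_is_an_error(self):
        lib = ReadLibrary([])
        lib.stage_depths = {"raw": 0, "contaminant_filtered": 0}
        with pytest.raises(ValueError):
            rpm(5, lib)

    def test_linearity(self):
        lib = ReadLibrary([])
        lib.stage_depths = {"raw": 12345, "contaminant_filtered": 12345}
        assert rpm(20, lib) == pytest.approx(2 * rpm(10, lib))


def test_stage_depths_monotone_through_cascade(small_sim):
    lib = smallrna.process_library(
        small_sim.library.reads,
        adapter=small_sim.scenario.adapter,
        contaminant_refs=small_sim.contaminant_refs,
        mirna_refs=small_sim.mirna_refs,
    )
    depths = list(lib.stage_depths.values())
    assert list(lib.stage_depths) == list(smallrna.STAGES)
    assert all(a >= b for a, b in zip(depths, depths[1:]))
    assert lib.normalization_depth == lib.stage_depths["contaminant_filtered"]
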