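import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utr5xpress.features import (
    FeatureConfig,
    FeatureGroup,
    codon_usage,
    extract_features,
    fold_descriptors,
    gc_metrics,
    kmer_frequencies,
    single_record_features,
    upstream_aug_count,
)
from utr5xpress.io_dataset import Dataset, UTRRecord

sequences = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestKmerFrequencies:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("ACGT", 1, {"kmer1_A": 0.25, "kmer1_C": 0.25, "kmer1_G": 0.25, "kmer1_T": 0.25}),
            ("AAAA", 2, {"kmer2_AA": 1.0}),
            # 5 windows of ACGTACGT counted by hand: ACGT x2, CGTA/GTAC/TACG x1
            (
                "ACGTACGT",
                4,
                {"kmer4_ACGT": 2 / 5, "kmer4_CGTA": 1 / 5, "kmer4_GTAC": 1 / 5, "kmer4_TACG": 1 / 5},
            ),
        ],
    )
    def test_hand_counted_examples(self, seq, k, expected):
        out = kmer_frequencies(seq, k, k)
        for name, value in expected.items():
            assert out[name] == pytest.approx(value)
        others = {k_: v for k_, v in out.items() if k_ not in expected}
        assert all(v == 0 for v in others.values())

    @given(seq=sequences, k=st.integers(1, 4))
    @settings(max_examples=50, deadline=None)
    def test_per_k_frequencies_sum_to_one(self, seq, k):
        out = kmer_frequencies(seq, k, k)
        total = sum(out.values())
        if len(seq) >= k:
            assert total == pytest.approx(1.0, abs=1e-9)
        else:
            assert total == 0.0

    def test_too_long_kmers_all_zero(self):
        out = kmer_frequencies("ACG", 4, 4)
        assert set(out.values()) == {0.0}
        assert len(out) == 256

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            kmer_frequencies("", 1, 2)


class TestGCMetrics:
    @pytest.mark.parametrize(
        "seq,gc,at",
        [("GGCC", 1.0, 0.0), ("ATAT", 0.0, 1.0), ("ACGG", 0.75, 0.25)],
    )
    def test_content_hand_counts(self, seq, gc, at):
        out = gc_metrics(seq)
        assert out["gc_content"] == pytest.approx(gc)
        assert out["at_ratio"] == pytest.approx(at)

    def test_cg_ratio(self):
        assert gc_metrics("ACGG")["cg_ratio"] == pytest.approx(0.5)

    def test_cg_ratio_g_free_falls_back_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert gc_metrics("ACCT")["cg_ratio"] == 0.0

    @given(seq=sequences)
    @settings(max_examples=50, deadline=None)
    def test_gc_plus_at_is_one(self, seq):
        out = gc_metrics(seq)
        assert out["gc_content"] + out["at_ratio"] == pytest.approx(1.0)

    @given(seq=sequences)
    @settings(max_examples=30, deadline=None)
    def test_gc_content_invariant_under_reverse_complement(self, seq):
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert gc_metrics(rc)["gc_content"] == pytest.approx(gc_metrics(seq)["gc_content"])


class TestUpstreamAUG:
    @pytest.mark.parametrize(
        "seq,count",
        [("CCCATGCC", 1), ("ATGATG", 2), ("CCCCCC", 0), ("ATGTGATGATG", 3), ("ATATGTG", 1)],
    )
    def test_counts(self, seq, count):
        assert upstream_aug_count(seq) == count

    def test_overlapping_occurrences_counted(self):
        assert upstream_aug_count("ATATGATGTG" + "ATGATGATG") == 2 + 3


class TestCodonUsage:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGATG", {"codon_ATG": 1.0}),
            ("ATGA", {"codon_ATG": 1.0}),  # trailing partial codon ignored
            ("AAACCC", {"codon_AAA": 0.5, "codon_CCC": 0.5}),
        ],
    )
    def test_frame0_nonoverlapping(self, seq, expected):
        out = codon_usage(seq)
        for name, value in expected.items():
            assert out[name] == pytest.approx(value)
        assert sum(out.values()) == pytest.approx(1.0)

    def test_short_sequence_zero_vector(self):
        out = codon_usage("AC")
        assert set(out.values()) == {0.0}


class TestFoldDescriptors:
    def test_unpairable_homopolymer(self):
        fold = fold_descriptors("AAAAAAAAAA")
        assert fold.mfe == 0.0
        assert fold.gquad_energy == 0.0
        assert fold.mean_bp_distance == 0.0

    def test_strong_hairpin_has_negative_mfe(self):
        assert fold_descriptors("GGGGAAAACCCC").mfe < 0

    def test_g_free_sequence_has_zero_gquad_energy(self):
        fold = fold_descriptors("ATCATCATCATCATCATC")
        assert fold.gquad_energy == 0.0

    def test_gquad_only_stabilizes(self, rng):
        # enabling an additional stabilizing motif class can only lower MFE
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            fold = fold_descriptors(seq)
            assert fold.mfe_gquad <= fold.mfe + 1e-9
            assert fold.gquad_energy <= 0.0

    def test_quadruplex_prone_sequence_gains_energy(self):
        # two-tier G-runs with short loops: a canonical quadruplex motif
        fold = fold_descriptors("GGTTGGTTGGTTGGTTGGAAGG")
        assert fold.gquad_energy < 0


class TestExtractFeatures:
    def test_column_count_matches_config(self, toy_dataset):
        matrix, manifest = extract_features(toy_dataset, FeatureConfig(k_max=2))
        # 4 + 16 k-mers, 3 GC metrics, 1 AUG count, 64 codons, 3 structure
        assert matrix.shape == (3, 4 + 16 + 3 + 1 + 64 + 3)
        assert list(matrix.columns) == list(manifest)

    def test_groups_assigned(self, toy_dataset):
        _, manifest = extract_features(toy_dataset, FeatureConfig(k_max=1))
        assert manifest["kmer1_A"] is FeatureGroup.SEQUENCE
        assert manifest["codon_ATG"] is FeatureGroup.CODON
        assert manifest["MFE"] is FeatureGroup.STRUCTURE
        assert manifest["mean_distance"] is FeatureGroup.STRUCTURE

    def test_deterministic(self, toy_dataset):
        m1, _ = extract_features(toy_dataset, FeatureConfig(k_max=2))
        m2, _ = extract_features(toy_dataset, FeatureConfig(k_max=2))
        assert m1.equals(m2)

    def test_row_order_follows_dataset_order(self, toy_dataset):
        matrix, _ = extract_features(toy_dataset, FeatureConfig(k_max=1, include_structure=False))
        permuted = Dataset(list(reversed(toy_dataset.records)))
        matrix_p, _ = extract_features(permuted, FeatureConfig(k_max=1, include_structure=False))
        assert list(matrix_p.index) == list(reversed(matrix.index))
        assert np.allclose(matrix_p.to_numpy(), matrix.to_numpy()[::-1])

    def test_empty_dataset_keeps_manifest(self):
        matrix, manifest = extract_features(Dataset([]), FeatureConfig(k_max=1))
        assert matrix.shape == (0, len(manifest))

    def test_all_values_finite(self, toy_dataset):
        matrix, _ = extract_features(toy_dataset)
        assert np.all(np.isfinite(matrix.to_numpy()))
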