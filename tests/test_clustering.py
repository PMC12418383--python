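import numpy as np
import pytest

from utr5xpress.clustering import (
    SimilarityParams,
    build_test_set,
    compression_metrics,
    greedy_cluster,
    pairwise_identity,
    select_count,
    select_percentage,
)
from utr5xpress.io_dataset import Dataset, UTRRecord
from utr5xpress.synthetic_data import SyntheticSpec, plant_clusters

from conftest import random_sequence


def brute_force_reference(dataset, threshold):
    """Literal restatement of the greedy incremental procedure, no shortcuts.

    Kept deliberately naive and separate from the library implementation:
    sort longest first (ids break ties), walk the existing representatives
    in creation order, join the first that reaches the threshold, else open
    a new cluster.  Returns the partition as a list of id lists.
    """
    ordered = sorted(dataset.records, key=lambda r: (-len(r.sequence), r.id))
    representatives = []  # (id, sequence)
    members = []
    for record in ordered:
        placed = False
        for idx, (_, rep_seq) in enumerate(representatives):
            if pairwise_identity(record.sequence, rep_seq) >= threshold:
                members[idx].append(record.id)
                placed = True
                break
        if not placed:
            representatives.append((record.id, record.sequence))
            members.append([record.id])
    return members


class TestPairwiseIdentity:
    def test_self_identity(self, rng):
        for _ in range(5):
            s = random_sequence(rng, int(rng.integers(10, 80)))
            assert pairwise_identity(s, s) == 1.0

    def test_disjoint_alphabets(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_single_substitution_on_8mer(self):
        assert pairwise_identity("ACGTACGT", "ACGAACGT") == pytest.approx(7 / 8)

    def test_symmetric(self, rng):
        for _ in range(20):
            a = random_sequence(rng, int(rng.integers(10, 60)))
            b = random_sequence(rng, int(rng.integers(10, 60)))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_bounded(self, rng):
        for _ in range(20):
            a = random_sequence(rng, int(rng.integers(10, 60)))
            b = random_sequence(rng, int(rng.integers(10, 60)))
            assert 0.0 <= pairwise_identity(a, b) <= 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self):
        ds = Dataset([UTRRecord(f"s{i}", "ACGTACGTACGT") for i in range(3)])
        clustering = greedy_cluster(ds)
        assert len(clustering) == 1
        assert len(clustering.clusters[0]) == 3

    def test_dissimilar_homopolymers_stay_apart(self):
        ds = Dataset([UTRRecord("a", "A" * 40), UTRRecord("t", "T" * 40)])
        clustering = greedy_cluster(ds, SimilarityParams(threshold=0.5))
        assert len(clustering) == 2

    def test_representative_is_longest_member(self, rng):
        seed = random_sequence(rng, 60)
        ds = Dataset(
            [
                UTRRecord("short", seed[:40]),
                UTRRecord("long", seed),
                UTRRecord("mid", seed[:50]),
            ]
        )
        clustering = greedy_cluster(ds, SimilarityParams(threshold=0.6))
        assert clustering.clusters[0].representative_id == "long"
        assert clustering.clusters[0].member_ids[0] == "long"

    def test_partition_property(self, rng):
        ds = Dataset(
            [UTRRecord(f"s{i}", random_sequence(rng, int(rng.integers(20, 60)))) for i in range(40)]
        )
        clustering = greedy_cluster(ds)
        members = [m for c in clustering.clusters for m in c.member_ids]
        assert sorted(members) == sorted(ds.ids())

    @pytest.mark.parametrize("threshold", [0.3, 0.5, 0.8])
    def test_matches_brute_force_reference(self, rng, threshold):
        for _ in range(10):
            n = int(rng.integers(5, 50))
            ds = Dataset(
                [
                    UTRRecord(f"s{i}", random_sequence(rng, int(rng.integers(20, 60))))
                    for i in range(n)
                ]
            )
            clustering = greedy_cluster(ds, SimilarityParams(threshold=threshold))
            assert [c.member_ids for c in clustering.clusters] == brute_force_reference(
                ds, threshold
            )

    def test_threshold_monotonicity(self, rng):
        ds = Dataset(
            [UTRRecord(f"s{i}", random_sequence(rng, int(rng.integers(30, 70)))) for i in range(30)]
        )
        sizes = [
            len(greedy_cluster(ds, SimilarityParams(threshold=t)))
            for t in (0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert sizes == sorted(sizes)

    def test_planted_structure_recovered(self):
        spec = SyntheticSpec(
            n_cluster_seeds=5, members_per_seed=8, mutation_rate=0.1, seed=3
        )
        ds, truth = plant_clusters(spec)
        clustering = greedy_cluster(ds, SimilarityParams(threshold=0.5))
        assert len(clustering) == 5
        found = clustering.membership()
        # same partition: every true family maps to exactly one found cluster
        for family in set(truth.values()):
            ids = {i for i, f in truth.items() if f == family}
            assert len({found[i] for i in ids}) == 1


class TestSelection:
    def _clustering(self, sizes, rng):
        records, clusters = [], []
        for ci, size in enumerate(sizes):
            seed = random_sequence(rng, 60)
            ids = []
            for mi in range(size):
                rid = f"c{ci}m{mi}"
                records.append(UTRRecord(rid, seed))
                ids.append(rid)
            clusters.append(ids)
        ds = Dataset(records)
        from utr5xpress.clustering import Cluster, Clustering

        return Clustering(
            [Cluster(ids[0], ids) for ids in clusters], SimilarityParams(), n_input=len(records)
        )

    def test_test_set_excludes_singletons(self, rng):
        clustering = self._clustering([3, 2, 1], rng)
        ids = build_test_set(clustering)
        assert ids == ["c0m0", "c1m0"]

    def test_all_singletons_empty_test_set(self, rng, caplog):
        clustering = self._clustering([1, 1], rng)
        with caplog.at_level("WARNING"):
            assert build_test_set(clustering) == []

    def test_percentage_full_fraction_returns_everything(self, rng):
        clustering = self._clustering([4, 3], rng)
        ids = select_percentage(clustering, 1.0, seed=0)
        assert sorted(ids) == sorted(m for c in clustering.clusters for m in c.member_ids)

    def test_percentage_ceil_rule(self, rng):
        clustering = self._clustering([4], rng)
        assert len(select_percentage(clustering, 0.5, seed=0)) == 2
        assert len(select_percentage(clustering, 0.1, seed=0)) == 1  # ceil never 0

    def test_count_caps_large_and_keeps_small_clusters(self, rng):
        clustering = self._clustering([10, 3], rng)
        ids = select_count(clustering, per_cluster=6, seed=0)
        by_cluster = [sum(i.startswith("c0") for i in ids), sum(i.startswith("c1") for i in ids)]
        assert by_cluster == [6, 3]

    def test_exclusions_respected(self, rng):
        clustering = self._clustering([5], rng)
        exclude = ["c0m0"]
        ids = select_count(clustering, per_cluster=6, seed=0, exclude=exclude)
        assert "c0m0" not in ids
        assert len(ids) == 4

    @pytest.mark.parametrize("selector,param", [(select_percentage, 0.5), (select_count, 2)])
    def test_selection_deterministic_in_seed(self, rng, selector, param):
        clustering = self._clustering([6, 4], rng)
        assert selector(clustering, param, seed=7) == selector(clustering, param, seed=7)
        assert selector(clustering, param, seed=7) != selector(clustering, param, seed=8)


class TestCompressionMetrics:
    def test_reference_sizes(self):
        out = compression_metrics(5838, 2468, 0.9, 0.84)
        assert out["compression_rate"] == pytest.approx(1 - 2468 / 5838)
        assert out["compression_rate"] == pytest.approx(0.577, abs=1e-3)

    def test_identity_subset(self):
        out = compression_metrics(100, 100, 0.7, 0.7)
        assert out == {"compression_rate": 0.0, "accuracy_restoration": 1.0}

    def test_half_restoration(self):
        assert compression_metrics(10, 5, 0.8, 0.4)["accuracy_restoration"] == pytest.approx(0.5)

    def test_zero_r_full_rejected(self):
        with pytest.raises(ValueError):
            compression_metrics(10, 5, 0.0, 0.1)


class TestWriters:
    def test_tsv_and_clstr_layouts(self, rng, tmp_path):
        from utr5xpress.clustering import write_clstr, write_clustering

        seed = random_sequence(rng, 40)
        ds = Dataset([UTRRecord("long", seed + "ACGT"), UTRRecord("short", seed)])
        clustering = greedy_cluster(ds, SimilarityParams(threshold=0.6))
        tsv = tmp_path / "clusters.tsv"
        write_clustering(clustering, tsv)
        lines = tsv.read_text().splitlines()
        assert lines[0] == "member_id\tcluster_index\tis_representative"
        assert lines[1].startswith("long\t0\t1")

        clstr = tmp_path / "clusters.clstr"
        write_clstr(clustering, ds, clstr)
        text = clstr.read_text()
        assert text.startswith(">Cluster 0")
        assert "44nt, >long... *" in text
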