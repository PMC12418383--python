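"""Greedy incremental sequence clustering and dataset compression.

Redundant 5'UTR libraries can be compressed without losing regulatory
diversity: sequences are sorted longest-first and each one either joins the
first existing cluster whose representative it matches at or above an
identity threshold, or founds a new cluster as its representative (the
CD-HIT strategy).  Cluster representatives of non-singleton clusters form a
maximally diverse held-out test set, and training subsets are drawn from
each cluster either as a fixed percentage or as a fixed count per cluster.

Identity between two sequences is the number of identically aligned
positions in an optimal global alignment divided by the length of the
shorter sequence (configurable to alignment-length normalization).  The
default alignment scoring (match +1, mismatch -2, gap open -15, gap extend
-0.2) penalizes mismatches and gap openings heavily, so unrelated
nucleotide sequences score well below a 0.5 threshold while substitution
mutants score near 1 - mutation rate; a unit-cost edit-distance alignment
("edit" scheme, via edlib) is available but inflates the chance identity of
unrelated sequences to ~0.55 and is unusable with thresholds that low.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal, Sequence

import edlib
import numpy as np
from Bio import Align

from .io_dataset import Dataset

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

#: (match, mismatch, gap open, gap extend) of the default global aligner.
DEFAULT_SCORING: tuple[float, float, float, float] = (1.0, -2.0, -15.0, -0.2)


@dataclass(frozen=True)
class SimilarityParams:
    """Identity threshold, metric convention and scoring for clustering."""

    threshold: float = 0.5
    identity: Literal["shorter", "alignment"] = "shorter"
    scheme: Literal["affine", "edit"] = "affine"
    best_match: bool = False  # join best-scoring cluster instead of first passing

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


@dataclass
class Cluster:
    """One cluster; the representative (longest member) is member_ids[0]."""

    representative_id: str
    member_ids: list[str]

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class Clustering:
    clusters: list[Cluster]
    params: SimilarityParams
    n_input: int = 0

    def __len__(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        """id -> cluster index."""
        return {
            m: i for i, cluster in enumerate(self.clusters) for m in cluster.member_ids
        }


@lru_cache(maxsize=4)
def _affine_aligner(scoring: tuple[float, float, float, float]) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    (
        aligner.match_score,
        aligner.mismatch_score,
        aligner.open_gap_score,
        aligner.extend_gap_score,
    ) = scoring
    return aligner


@lru_cache(maxsize=1 << 18)
def _matches_and_length(a: str, b: str, scheme: str) -> tuple[int, int]:
    """(identical aligned positions, alignment length) of an optimal global alignment."""
    if scheme == "edit":
        res = edlib.align(a, b, mode="NW", task="path")
        matches = aln_len = 0
        for n, op in _CIGAR_RE.findall(res["cigar"]):
            n = int(n)
            aln_len += n
            if op == "=":
                matches += n
        return matches, aln_len
    alignment = _affine_aligner(DEFAULT_SCORING).align(a, b)[0]
    counts = alignment.counts()
    return counts.identities, alignment.length


def pairwise_identity(
    a: str,
    b: str,
    identity: Literal["shorter", "alignment"] = "shorter",
    scheme: Literal["affine", "edit"] = "affine",
) -> float:
    """Global-alignment identity between two sequences, in [0, 1].

    Identical aligned positions of an optimal global alignment (affine-gap
    scoring by default, minimum-edit-distance with ``scheme="edit"``)
    divided by the shorter sequence length (default) or the alignment
    length.  Arguments are ordered canonically first, so the function is
    exactly symmetric; results are memoized.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if (len(a), a) > (len(b), b):
        a, b = b, a
    matches, aln_len = _matches_and_length(a, b, scheme)
    denom = len(a) if identity == "shorter" else aln_len
    return min(matches / denom, 1.0)


def _sorted_longest_first(dataset: Dataset) -> list:
    # length-descending; ties broken lexicographically by id for determinism
    return sorted(dataset.records, key=lambda r: (-len(r.sequence), r.id))


def greedy_cluster(dataset: Dataset, params: SimilarityParams | None = None) -> Clustering:
    """Single-pass greedy incremental clustering, longest sequence first.

    Each sequence is compared against existing cluster representatives in
    creation order and joins the first one reaching the identity threshold
    (or the best-scoring one with ``params.best_match``); otherwise it
    founds a new cluster.  Deterministic for a fixed input.
    """
    params = params or SimilarityParams()
    if len(dataset) == 0:
        raise ValueError("cannot cluster an empty dataset")
    clusters: list[Cluster] = []
    reps: list[str] = []  # representative sequences, parallel to clusters
    for rec in _sorted_longest_first(dataset):
        target = None
        if params.best_match:
            best_ident, target = -1.0, None
            for i, rep_seq in enumerate(reps):
                ident = pairwise_identity(rec.sequence, rep_seq, params.identity, params.scheme)
                if ident >= params.threshold and ident > best_ident:
                    best_ident, target = ident, i
        else:
            for i, rep_seq in enumerate(reps):
                if (
                    pairwise_identity(rec.sequence, rep_seq, params.identity, params.scheme)
                    >= params.threshold
                ):
                    target = i
                    break
        if target is None:
            clusters.append(Cluster(rec.id, [rec.id]))
            reps.append(rec.sequence)
        else:
            clusters[target].member_ids.append(rec.id)
    return Clustering(clusters, params, n_input=len(dataset))


def build_test_set(clustering: Clustering) -> list[str]:
    """Representatives of all non-singleton clusters (a diversity-maximal test set).

    Singletons are excluded: their cluster contributes no training
    neighbors, so a model has nothing to learn them from.
    """
    ids = [c.representative_id for c in clustering.clusters if len(c) >= 2]
    if not ids:
        logger.warning("all clusters are singletons; test set is empty")
    return ids


def _cluster_pool(cluster: Cluster, exclude: set[str]) -> list[str]:
    return [m for m in cluster.member_ids if m not in exclude]


def select_percentage(
    clustering: Clustering,
    fraction: float,
    seed: int,
    exclude: Iterable[str] = (),
) -> list[str]:
    """From each cluster, sample ceil(fraction * remaining) members.

    ``exclude`` (typically the test representatives) is removed first; the
    ceil rule guarantees every cluster with remaining members contributes at
    least one sequence.  Pure function of (clustering, fraction, seed).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    excl = set(exclude)
    chosen: list[str] = []
    for cluster in clustering.clusters:
        pool = _cluster_pool(cluster, excl)
        if not pool:
            continue
        k = math.ceil(fraction * len(pool))
        chosen.extend(rng.choice(pool, size=k, replace=False).tolist())
    return chosen


def select_count(
    clustering: Clustering,
    per_cluster: int = 6,
    seed: int = 0,
    exclude: Iterable[str] = (),
) -> list[str]:
    """From each cluster, sample min(per_cluster, available) members.

    Caps the contribution of huge clusters, which dominate percentage-based
    selection; small clusters are kept whole.
    """
    if per_cluster < 1:
        raise ValueError("per_cluster must be >= 1")
    rng = np.random.default_rng(seed)
    excl = set(exclude)
    chosen: list[str] = []
    for cluster in clustering.clusters:
        pool = _cluster_pool(cluster, excl)
        if not pool:
            continue
        k = min(per_cluster, len(pool))
        chosen.extend(rng.choice(pool, size=k, replace=False).tolist())
    return chosen


def compression_metrics(
    full_n: int, subset_n: int, r_full: float, r_subset: float
) -> dict[str, float]:
    """Dataset compression rate and accuracy restoration of a training subset.

    compression_rate = 1 - subset_n / full_n;
    accuracy_restoration = r_subset / r_full.
    """
    if full_n <= 0:
        raise ValueError("full_n must be positive")
    if r_full == 0:
        raise ValueError("accuracy restoration undefined for r_full = 0")
    return {
        "compression_rate": 1.0 - subset_n / full_n,
        "accuracy_restoration": r_subset / r_full,
    }


def write_clustering(clustering: Clustering, path: str | Path) -> None:
    """TSV: member_id, cluster_index, is_representative."""
    with open(path, "w") as fh:
        fh.write("member_id\tcluster_index\tis_representative\n")
        for i, cluster in enumerate(clustering.clusters):
            for m in cluster.member_ids:
                fh.write(f"{m}\t{i}\t{int(m == cluster.representative_id)}\n")


def write_clstr(clustering: Clustering, dataset: Dataset, path: str | Path) -> None:
    """CD-HIT ``.clstr``-style text layout."""
    lengths = {r.id: len(r.sequence) for r in dataset}
    with open(path, "w") as fh:
        for i, cluster in enumerate(clustering.clusters):
            fh.write(f">Cluster {i}\n")
            for j, m in enumerate(cluster.member_ids):
                mark = "*" if m == cluster.representative_id else ""
                fh.write(f"{j}\t{lengths.get(m, 0)}nt, >{m}... {mark}\n")
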