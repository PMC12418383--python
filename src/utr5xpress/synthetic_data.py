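"""Synthetic 5'UTR libraries with known ground truth.

Generators for every kind of input the toolkit consumes: random UTR
sequences with a controllable GC bias, planted sequence-similarity cluster
structure (dissimilar seed sequences expanded into point-mutant families),
TE labels produced as a known linear function of extracted features plus
Gaussian noise, and replicate-plate bioluminescence tables with reference
wells.  Every generator is a pure function of its spec and seed, so tests
and experiments are exactly reproducible.

The generated data mimics the statistical structure of endogenous 5'UTR
libraries — redundancy through families of near-identical sequences,
log-scale labels driven by composition and folding energy — not the
nucleotide-level composition of any real transcriptome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FeatureConfig, extract_features
from .io_dataset import Dataset, UTRRecord

BASES = np.array(list("ACGT"))

#: Default TE model: folding stability suppresses expression (low MFE = stable
#: structure = poor ribosome access), GC content suppresses, upstream AUGs
#: suppress.  Weights act on z-scored features, labels live on a log scale.
DEFAULT_TE_WEIGHTS: dict[str, float] = {
    "MFE": 1.0,
    "gc_content": -0.8,
    "uAUG_count": -0.6,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic 5'UTR library.

    ``members_per_seed`` may be a single int (equal-sized families) or a
    tuple with one entry per seed; real libraries have heavily skewed
    family sizes, which is what makes per-cluster capped selection differ
    from random subsampling.
    """

    n_sequences: int = 100
    length_min: int = 50
    length_max: int = 100
    gc_bias: float = 0.5
    n_cluster_seeds: int = 10
    members_per_seed: int | tuple[int, ...] = 20
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_min < 10:
            raise ValueError("lengths must be >= 10")
        if self.length_max > 200 or self.length_max < self.length_min:
            raise ValueError("need length_min <= length_max <= 200")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if not 0 < self.gc_bias < 1:
            raise ValueError("gc_bias must be in (0, 1)")
        if isinstance(self.members_per_seed, tuple) and len(
            self.members_per_seed
        ) != self.n_cluster_seeds:
            raise ValueError("members_per_seed tuple must have one entry per seed")

    def family_sizes(self) -> list[int]:
        if isinstance(self.members_per_seed, tuple):
            return list(self.members_per_seed)
        return [self.members_per_seed] * self.n_cluster_seeds


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def generate_utrs(spec: SyntheticSpec) -> Dataset:
    """Random UTR sequences: lengths uniform in range, bases i.i.d. at the GC bias."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_sequences):
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        records.append(
            UTRRecord(id=f"utr{i:05d}", sequence=_random_sequence(rng, length, spec.gc_bias))
        )
    return Dataset(records, provenance=f"synthetic generate_utrs(seed={spec.seed})")


def mutate_sequence(rng: np.random.Generator, sequence: str, rate: float) -> str:
    """Per-base substitution at ``rate``; a substitution always changes the base.

    Expected identity to the parent is therefore exactly 1 - rate.
    """
    arr = np.array(list(sequence))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        alternatives = BASES[BASES != arr[i]]
        arr[i] = rng.choice(alternatives)
    return "".join(arr)


def plant_clusters(spec: SyntheticSpec, max_seed_draws: int = 100) -> tuple[Dataset, dict[str, int]]:
    """Seed sequences expanded into point-mutant families, with truth labels.

    Seeds are redrawn (up to ``max_seed_draws`` times) until all pairwise
    identities are below 0.3, so the planted families are unambiguous.
    Returns the dataset (seeds + mutants) and an id -> family-index map.
    """
    from .clustering import pairwise_identity

    rng = np.random.default_rng(spec.seed)
    seeds: list[str] = []
    draws = 0
    while len(seeds) < spec.n_cluster_seeds and draws < max_seed_draws:
        draws += 1
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        cand = _random_sequence(rng, length, spec.gc_bias)
        if all(pairwise_identity(cand, s) < 0.3 for s in seeds):
            seeds.append(cand)
    if len(seeds) < spec.n_cluster_seeds:
        raise RuntimeError(
            f"could not draw {spec.n_cluster_seeds} mutually dissimilar seeds "
            f"in {max_seed_draws} attempts"
        )
    records, truth = [], {}
    for k, (seed_seq, size) in enumerate(zip(seeds, spec.family_sizes())):
        rid = f"c{k:03d}_seed"
        records.append(UTRRecord(id=rid, sequence=seed_seq))
        truth[rid] = k
        for m in range(size):
            rid = f"c{k:03d}_m{m:03d}"
            records.append(
                UTRRecord(id=rid, sequence=mutate_sequence(rng, seed_seq, spec.mutation_rate))
            )
            truth[rid] = k
    return Dataset(records, provenance=f"synthetic plant_clusters(seed={spec.seed})"), truth


def noise_sd_for_r2(signal: np.ndarray, r2: float) -> float:
    """Noise s.d. giving the requested population R^2 for a known signal.

    R^2 = var(signal) / (var(signal) + sd^2)  =>  sd = sd(signal) * sqrt(1/R^2 - 1).
    """
    if not 0 < r2 <= 1:
        raise ValueError("r2 must be in (0, 1]")
    return float(np.std(signal) * np.sqrt(1 / r2 - 1))


def simulate_te(
    dataset: Dataset,
    te_model: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
    target_r2: float | None = None,
    features_matrix=None,
    family_map: dict[str, int] | None = None,
    family_sd: float = 0.0,
) -> tuple[Dataset, dict]:
    """Attach TE labels generated as a linear function of extracted features.

    te = sum_f w_f * zscore(feature_f) [+ family effect] + Normal(0, noise_sd).
    When ``target_r2`` is given, noise_sd is derived from the realized
    signal variance instead.  RPKM values are drawn uniformly in (10, 100]
    so the abundance filter keeps everything unless a test plants
    violations.

    ``family_map`` (id -> family index, e.g. the truth table from
    :func:`plant_clusters`) with ``family_sd`` > 0 adds a shared
    Normal(0, family_sd) offset per sequence family.  This emulates the
    premise behind clustering-based dataset compression: similar sequences
    share regulatory behavior beyond what global descriptors explain, so a
    family unseen in training is genuinely unpredictable.

    Returns the labeled dataset and a ground-truth dict (weights, noise_sd,
    family effects, per-record signal).
    """
    te_model = dict(te_model or DEFAULT_TE_WEIGHTS)
    feature_config = feature_config or FeatureConfig()
    if features_matrix is not None:
        matrix = features_matrix.loc[dataset.ids()]
    else:
        matrix, _ = extract_features(dataset, feature_config)
    unknown = set(te_model) - set(matrix.columns)
    if unknown:
        raise KeyError(f"te_model references unknown features: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    signal = np.zeros(len(dataset))
    for name, weight in te_model.items():
        col = matrix[name].to_numpy()
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        signal += weight * z
    family_effects: dict[int, float] = {}
    if family_map is not None and family_sd > 0:
        families = sorted(set(family_map.values()))
        draws = rng.normal(0.0, family_sd, size=len(families))
        family_effects = dict(zip(families, draws.tolist()))
        signal = signal + np.array(
            [family_effects[family_map[i]] for i in dataset.ids()]
        )
    if target_r2 is not None:
        noise_sd = noise_sd_for_r2(signal, target_r2)
    te = signal + rng.normal(0.0, noise_sd, size=len(dataset))
    rpkm = rng.uniform(10.0, 100.0, size=len(dataset))
    rpkm = np.nextafter(rpkm, np.inf)  # strictly above 10 even at the draw boundary
    records = [
        replace(rec, te_value=float(te[i]), rpkm=float(rpkm[i]))
        for i, rec in enumerate(dataset)
    ]
    truth = {
        "weights": te_model,
        "noise_sd": float(noise_sd),
        "family_effects": family_effects,
        "signal": dict(zip(dataset.ids(), signal.tolist())),
    }
    labeled = Dataset(records, provenance=f"{dataset.provenance} + simulate_te(seed={seed})")
    return labeled, truth


def motif_count_library(
    n_sequences: int = 500,
    length: int = 60,
    motif: str = "TACGA",
    max_count: int = 5,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Sequences whose label is the planted occurrence count of a motif.

    Each sequence is random with 0..max_count copies of ``motif`` planted at
    disjoint offsets; the label is the realized total count (spontaneous
    extra occurrences included, so labels are exact).  A direct sanity task
    for sequence-to-expression networks: the signal is local, additive and
    position-independent.
    """
    rng = np.random.default_rng(seed)
    slots = list(range(0, length - len(motif), len(motif) + 1))
    sequences, labels = [], []
    for _ in range(n_sequences):
        k = int(rng.integers(0, max_count + 1))
        seq = list("".join(rng.choice(BASES, size=length)))
        for pos in rng.choice(slots, size=k, replace=False):
            seq[pos : pos + len(motif)] = list(motif)
        seq = "".join(seq)
        sequences.append(seq)
        labels.append(seq.count(motif))
    return sequences, np.array(labels, dtype=float)


def simulate_plates(
    abi_truth: dict[str, float],
    n_plates: int = 3,
    cv: float = 0.0,
    seed: int = 0,
    n_technical: int = 2,
    reference_id: str = "REF",
) -> pd.DataFrame:
    """Replicate-plate bioluminescence table for known true expression ratios.

    Each plate gets a reference well (signal drawn lognormally around 1e5
    counts); each sample's well signal is true_ratio * reference *
    lognormal(cv), read ``n_technical`` times.  With cv = 0,
    :func:`utr5xpress.abi.compute_abi` recovers the truth exactly.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_plates):
        plate_id = f"plate{p + 1}"
        ref_signal = float(1e5 * rng.lognormal(0.0, 0.1))
        wells = [(reference_id, 1.0, True)] + [
            (sid, ratio, False) for sid, ratio in abi_truth.items()
        ]
        for w, (sid, ratio, is_ref) in enumerate(wells):
            # the reference well sets the plate scale exactly; measurement
            # noise applies to the experimental wells
            noise = rng.lognormal(0.0, cv) if (cv > 0 and not is_ref) else 1.0
            mean_signal = ratio * ref_signal * noise
            for rep in range(1, n_technical + 1):
                rows.append(
                    {
                        "plate_id": plate_id,
                        "well": f"{chr(65 + w // 12)}{w % 12 + 1:02d}",
                        "sample_id": sid,
                        "technical_rep": rep,
                        "signal": mean_signal,
                        "is_reference": int(is_ref),
                    }
                )
    return pd.DataFrame(rows)
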