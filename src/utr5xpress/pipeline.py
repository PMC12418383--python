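"""End-to-end dataset-compression experiments.

Orchestrates the full design used to evaluate clustering-based dataset
compression: cluster the library, hold out the cluster representatives as a
diversity-maximal test set, draw a training subset from the clusters
(percentage- or count-based), train a size-matched randomly selected
control, train the model on both, evaluate on the held-out representatives,
and report paired correlations plus compression/restoration metrics.
Everything is seeded; a run is exactly reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clustering as clust
from .clustering import Clustering, SimilarityParams, compression_metrics
from .evaluation import pearson_r
from .features import FeatureConfig, extract_features
from .io_dataset import Dataset
from .rf_model import RFHyperParams, predict_rf, train_rf
from .seqnet import SeqNetConfig, TrainConfig, predict_seqnet, train_seqnet

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    threshold: float = 0.5
    selection_mode: str = "count"  # "none" | "percentage" | "count"
    selection_param: float = 6  # fraction for percentage, k for count
    model: str = "rf"  # "rf" | "seqnet"
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    rf_params: RFHyperParams = field(default_factory=RFHyperParams)
    seqnet_config: SeqNetConfig = field(default_factory=SeqNetConfig.reduced)
    seqnet_train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection_mode not in ("none", "percentage", "count"):
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")
        if self.model not in ("rf", "seqnet"):
            raise ValueError(f"unknown model {self.model!r}")


def _train_predict(config: ExperimentConfig, train_ds: Dataset, test_ds: Dataset, X_all) -> np.ndarray:
    y_train = np.array([r.te_value for r in train_ds], dtype=float)
    if config.model == "rf":
        bundle = train_rf(X_all.loc[train_ds.ids()], y_train, config.rf_params)
        return predict_rf(bundle, X_all.loc[test_ds.ids()])
    trained = train_seqnet(
        train_ds.sequences(), y_train, config.seqnet_config, config.seqnet_train
    )
    return predict_seqnet(trained, test_ds.sequences())


def run_compression_experiment(
    dataset: Dataset,
    config: ExperimentConfig | None = None,
    features=None,
    clustering: Clustering | None = None,
) -> dict:
    """Cluster, select, train (subset + size-matched random control), evaluate.

    Returns a report dict with the clustering summary, the held-out
    representative test set, training-subset sizes, Pearson correlations of
    the full-data model, the cluster-guided subset model and the random
    control, and compression/restoration metrics.  Raises if any training
    subset leaks a test sequence.

    ``features`` (an id-indexed feature DataFrame covering the whole
    dataset) and ``clustering`` may be precomputed and reused across
    replicate runs; otherwise they are computed here.
    """
    config = config or ExperimentConfig()
    for rec in dataset:
        if rec.te_value is None:
            raise ValueError(f"record {rec.id!r} has no TE label")

    if config.model == "rf" and features is None:
        features, _ = extract_features(dataset, config.feature_config)
    if clustering is None:
        clustering = clust.greedy_cluster(dataset, SimilarityParams(threshold=config.threshold))
    test_ids = clust.build_test_set(clustering)
    if not test_ids:
        raise ValueError("clustering produced no non-singleton clusters; nothing to test on")
    test_ds = dataset.subset(test_ids)
    train_pool = [i for i in dataset.ids() if i not in set(test_ids)]

    if config.selection_mode == "none":
        subset_ids = list(train_pool)
    elif config.selection_mode == "percentage":
        subset_ids = clust.select_percentage(
            clustering, float(config.selection_param), seed=config.seed, exclude=test_ids
        )
    else:
        subset_ids = clust.select_count(
            clustering, int(config.selection_param), seed=config.seed, exclude=test_ids
        )

    leak = set(subset_ids) & set(test_ids)
    if leak:
        raise RuntimeError(f"test leakage: {sorted(leak)[:5]}")

    rng = np.random.default_rng(config.seed)
    random_ids = rng.choice(train_pool, size=len(subset_ids), replace=False).tolist()
    assert not set(random_ids) & set(test_ids)

    y_test = np.array([r.te_value for r in test_ds], dtype=float)
    r_full = pearson_r(_train_predict(config, dataset.subset(train_pool), test_ds, features), y_test)
    r_subset = pearson_r(_train_predict(config, dataset.subset(subset_ids), test_ds, features), y_test)
    r_random = pearson_r(_train_predict(config, dataset.subset(random_ids), test_ds, features), y_test)

    metrics = compression_metrics(len(train_pool), len(subset_ids), r_full, r_subset)
    return {
        "n_input": len(dataset),
        "n_clusters": len(clustering),
        "n_test": len(test_ids),
        "n_train_full": len(train_pool),
        "n_train_subset": len(subset_ids),
        "selection_mode": config.selection_mode,
        "selection_param": config.selection_param,
        "threshold": config.threshold,
        "model": config.model,
        "seed": config.seed,
        "r_full": r_full,
        "r_subset": r_subset,
        "r_random_control": r_random,
        "compression_rate": metrics["compression_rate"],
        "accuracy_restoration": metrics["accuracy_restoration"],
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))
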