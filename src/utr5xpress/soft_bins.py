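"""Soft-classification codec for continuous expression labels.

Instead of regressing a single value, the network predicts a probability
distribution over 29 discrete expression categories (bins 0..28).  A
continuous label ``e`` (already on the bin scale) is encoded as the
probability mass that a Normal(mu = e + 0.5, sd = 0.5) random variable
falls into each unit interval [i, i+1); the first and last categories
absorb the tails.  A predicted distribution is decoded back to a value as
its expectation over bin indices, and training compares target and
predicted distributions with the Kullback-Leibler divergence.

Because measured TE labels live on an arbitrary log scale, an explicit
affine ``label_map`` (te -> bin) is part of :class:`BinSpec`; it is fitted
to the training data (min -> 0, max -> n_bins-1 by default), saved with any
trained model, and exactly invertible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "BinSpec",
    "encode_expression",
    "decode_expression",
    "kl_divergence",
    "te_to_bin",
    "bin_to_te",
]

_SUM_TOL = 1e-9
_KL_FLOOR = 1e-12


@dataclass
class BinSpec:
    """Parameters of the expression-bin codec.

    ``label_map = (scale, shift)`` maps TE space to bin space as
    ``bin = scale * te + shift``; the inverse is exact.
    """

    n_bins: int = 29
    mu_offset: float = 0.5
    sigma: float = 0.5
    label_map: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.label_map[0] == 0:
            raise ValueError("label_map scale must be nonzero")

    @classmethod
    def fit(cls, te_values: Sequence[float], **kwargs) -> "BinSpec":
        """Spec whose label map sends min(te) -> bin 0 and max(te) -> last bin."""
        te = np.asarray(te_values, dtype=float)
        if te.size < 2 or np.ptp(te) == 0:
            raise ValueError("need at least two distinct TE values to fit a label map")
        spec = cls(**kwargs)
        scale = (spec.n_bins - 1) / (te.max() - te.min())
        shift = -scale * te.min()
        spec.label_map = (scale, shift)
        return spec

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_bins": self.n_bins,
                    "mu_offset": self.mu_offset,
                    "sigma": self.sigma,
                    "label_map": list(self.label_map),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BinSpec":
        d = json.loads(Path(path).read_text())
        d["label_map"] = tuple(d["label_map"])
        return cls(**d)


def te_to_bin(value: float | np.ndarray, spec: BinSpec) -> float | np.ndarray:
    """Affine map from TE space to bin space."""
    scale, shift = spec.label_map
    return scale * np.asarray(value, dtype=float) + shift


def bin_to_te(value: float | np.ndarray, spec: BinSpec) -> float | np.ndarray:
    """Exact inverse of :func:`te_to_bin`."""
    scale, shift = spec.label_map
    return (np.asarray(value, dtype=float) - shift) / scale


def encode_expression(e: float, spec: BinSpec | None = None) -> np.ndarray:
    """Encode a bin-space expression value as a soft category distribution.

    probs[i] = P(rho in [i, i+1)) for rho ~ Normal(e + mu_offset, sigma),
    with the first/last category absorbing the lower/upper tail.
    """
    spec = spec or BinSpec()
    if not math.isfinite(e):
        raise ValueError(f"expression value must be finite, got {e}")
    edges = np.arange(1, spec.n_bins, dtype=float)  # interior edges 1..n-1
    cdf = norm.cdf(edges, loc=e + spec.mu_offset, scale=spec.sigma)
    probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum()


def encode_batch(e: np.ndarray, spec: BinSpec | None = None) -> np.ndarray:
    """Vectorized :func:`encode_expression` over a 1-D array; rows sum to 1."""
    spec = spec or BinSpec()
    e = np.asarray(e, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("expression values must be finite")
    edges = np.arange(1, spec.n_bins, dtype=float)
    cdf = norm.cdf(edges[None, :], loc=(e + spec.mu_offset)[:, None], scale=spec.sigma)
    padded = np.concatenate(
        [np.zeros((len(e), 1)), cdf, np.ones((len(e), 1))], axis=1
    )
    probs = np.clip(np.diff(padded, axis=1), 0.0, None)
    return probs / probs.sum(axis=1, keepdims=True)


def _validate(dist: np.ndarray, name: str = "distribution") -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if np.any(dist < 0):
        raise ValueError(f"{name} has negative entries")
    if abs(dist.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} sums to {dist.sum():.6g}, not 1")
    return dist


def decode_expression(dist: np.ndarray, spec: BinSpec | None = None) -> float:
    """Expectation of the bin index under the distribution (bin space)."""
    spec = spec or BinSpec()
    dist = _validate(dist)
    if len(dist) != spec.n_bins:
        raise ValueError(f"expected {spec.n_bins} bins, got {len(dist)}")
    return float(dist @ np.arange(spec.n_bins))


def kl_divergence(target: np.ndarray, predicted: np.ndarray) -> float:
    """KL(target || predicted) with 0*log0 = 0 and predicted floored at 1e-12."""
    target = _validate(np.asarray(target), "target")
    predicted = _validate(np.asarray(predicted), "predicted")
    if target.shape != predicted.shape:
        raise ValueError(
            f"shape mismatch: target {target.shape} vs predicted {predicted.shape}"
        )
    pred = np.maximum(predicted, _KL_FLOOR)
    mask = target > 0
    return float(np.sum(target[mask] * np.log(target[mask] / pred[mask])))
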