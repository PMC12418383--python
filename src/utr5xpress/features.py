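"""Feature extraction for 5'UTR expression modeling.

Three groups of named features feed the randomized-tree regressor:

* SEQUENCE — k-mer frequencies (k = 1..6 by default), GC-content metrics
  (gc_content, at_ratio, cg_ratio) and the count of upstream AUG triplets
  (potential upstream-ORF starts that suppress main-ORF translation).
* CODON — frequencies of the 64 triplets read non-overlapping in frame 0
  from the 5' end of the UTR.
* STRUCTURE — thermodynamic descriptors from nearest-neighbor RNA folding
  at 37 degC: minimum free energy (MFE), the energy gain from allowing
  G-quadruplex motifs (Gquad_energy = MFE_gquad - MFE <= 0), and the
  Boltzmann-ensemble mean base-pair distance (mean_distance), a proxy for
  structural flexibility.

k-mer frequencies are window counts divided by (L - k + 1), so for every
sequence of length >= k the 4^k frequencies of one k sum to 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import RNA

from .io_dataset import Dataset

logger = logging.getLogger(__name__)

BASES = "ACGT"


class FeatureGroup(str, Enum):
    SEQUENCE = "SEQUENCE"
    STRUCTURE = "STRUCTURE"
    CODON = "CODON"


@dataclass(frozen=True)
class FoldingResult:
    """Thermodynamic descriptors of one sequence (kcal/mol, nt)."""

    mfe: float
    mfe_gquad: float
    mean_bp_distance: float

    @property
    def gquad_energy(self) -> float:
        """Energy gain from allowing G-quadruplexes; <= 0 by construction."""
        return min(self.mfe_gquad - self.mfe, 0.0)


@dataclass
class FeatureConfig:
    """What to extract.  Folding can be switched off for sequence-only runs."""

    k_min: int = 1
    k_max: int = 6
    include_structure: bool = True
    include_codon: bool = True
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("need 1 <= k_min <= k_max")


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(BASES)
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    return sequence


def kmer_frequencies(sequence: str, k_min: int = 1, k_max: int = 6) -> dict[str, float]:
    """Window frequencies of every k-mer for k in [k_min, k_max].

    Each k-mer's frequency is its count divided by the number of windows
    (L - k + 1); k-mers longer than the sequence get 0.  Keys look like
    ``kmer3_ACG``.
    """
    _check_sequence(sequence)
    L = len(sequence)
    out: dict[str, float] = {}
    for k in range(k_min, k_max + 1):
        counts: dict[str, int] = {}
        n_windows = L - k + 1
        if n_windows > 0:
            for i in range(n_windows):
                mer = sequence[i : i + k]
                counts[mer] = counts.get(mer, 0) + 1
        for mer_tuple in itertools.product(BASES, repeat=k):
            mer = "".join(mer_tuple)
            out[f"kmer{k}_{mer}"] = (
                counts.get(mer, 0) / n_windows if n_windows > 0 else 0.0
            )
    return out


def gc_metrics(sequence: str) -> dict[str, float]:
    """GC-content metrics: gc_content, at_ratio, cg_ratio (= #C / #G).

    ``cg_ratio`` falls back to 0 (with a warning) for G-free sequences so
    the feature matrix stays finite.
    """
    _check_sequence(sequence)
    L = len(sequence)
    n = {b: sequence.count(b) for b in BASES}
    if n["G"] > 0:
        cg_ratio = n["C"] / n["G"]
    else:
        logger.warning("cg_ratio undefined for G-free sequence; emitting 0")
        cg_ratio = 0.0
    return {
        "gc_content": (n["G"] + n["C"]) / L,
        "at_ratio": (n["A"] + n["T"]) / L,
        "cg_ratio": cg_ratio,
    }


def upstream_aug_count(sequence: str) -> int:
    """Number of ATG triplets anywhere in the UTR (overlapping counted)."""
    _check_sequence(sequence)
    count = start = 0
    while True:
        idx = sequence.find("ATG", start)
        if idx == -1:
            return count
        count += 1
        start = idx + 1


def codon_usage(sequence: str) -> dict[str, float]:
    """Frequencies of the 64 triplets, frame 0, non-overlapping, 5' to 3'.

    Normalized by the number of complete codons; a trailing partial codon is
    ignored, and sequences shorter than 3 nt yield the zero vector.
    """
    _check_sequence(sequence)
    n_codons = len(sequence) // 3
    counts: dict[str, int] = {}
    for i in range(n_codons):
        cod = sequence[3 * i : 3 * i + 3]
        counts[cod] = counts.get(cod, 0) + 1
    return {
        f"codon_{''.join(c)}": (
            counts.get("".join(c), 0) / n_codons if n_codons else 0.0
        )
        for c in itertools.product(BASES, repeat=3)
    }


def fold_descriptors(sequence: str, temperature: float = 37.0) -> FoldingResult:
    """Fold one sequence with the nearest-neighbor model (ViennaRNA).

    Returns the plain MFE, the MFE with G-quadruplex scoring enabled, and
    the ensemble mean base-pair distance from the partition function.
    """
    _check_sequence(sequence)
    rna = sequence.replace("T", "U")

    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(rna, md)
    _, mfe = fc.mfe()
    fc.exp_params_rescale(mfe)
    fc.pf()
    mean_dist = fc.mean_bp_distance()

    md_g = RNA.md()
    md_g.temperature = temperature
    md_g.gquad = 1
    fc_g = RNA.fold_compound(rna, md_g)
    _, mfe_gquad = fc_g.mfe()

    return FoldingResult(
        mfe=float(mfe),
        mfe_gquad=float(min(mfe_gquad, mfe)),
        mean_bp_distance=float(max(mean_dist, 0.0)),
    )


def single_record_features(
    sequence: str, config: FeatureConfig | None = None
) -> tuple[dict[str, float], dict[str, FeatureGroup]]:
    """Feature values and group manifest for one sequence."""
    config = config or FeatureConfig()
    values: dict[str, float] = {}
    groups: dict[str, FeatureGroup] = {}

    kmers = kmer_frequencies(sequence, config.k_min, config.k_max)
    values.update(kmers)
    groups.update({k: FeatureGroup.SEQUENCE for k in kmers})

    gc = gc_metrics(sequence)
    values.update(gc)
    groups.update({k: FeatureGroup.SEQUENCE for k in gc})

    values["uAUG_count"] = float(upstream_aug_count(sequence))
    groups["uAUG_count"] = FeatureGroup.SEQUENCE

    if config.include_codon:
        codons = codon_usage(sequence)
        values.update(codons)
        groups.update({k: FeatureGroup.CODON for k in codons})

    if config.include_structure:
        fold = fold_descriptors(sequence, config.temperature)
        structure = {
            "MFE": fold.mfe,
            "Gquad_energy": fold.gquad_energy,
            "mean_distance": fold.mean_bp_distance,
        }
        values.update(structure)
        groups.update({k: FeatureGroup.STRUCTURE for k in structure})

    return values, groups


def feature_manifest(config: FeatureConfig | None = None) -> dict[str, FeatureGroup]:
    """Column name -> group mapping for a config (no data needed)."""
    _, groups = single_record_features("ACGT", config)
    return groups


def extract_features(
    dataset: Dataset, config: FeatureConfig | None = None
) -> tuple[pd.DataFrame, dict[str, FeatureGroup]]:
    """Feature matrix for a dataset (rows = records, in dataset order).

    Returns a DataFrame indexed by record id together with the name->group
    manifest.  Deterministic for a fixed config; per-record failures are
    re-raised with the offending record id.
    """
    config = config or FeatureConfig()
    manifest = feature_manifest(config)
    rows = []
    for rec in dataset:
        try:
            values, _ = single_record_features(rec.sequence, config)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for {rec.id!r}: {exc}") from exc
        rows.append(values)
    matrix = pd.DataFrame(rows, index=pd.Index(dataset.ids(), name="id"), dtype=float)
    matrix = matrix.reindex(columns=list(manifest), fill_value=0.0)
    return matrix, manifest


def write_feature_matrix(
    matrix: pd.DataFrame, manifest: dict[str, FeatureGroup], path, manifest_path=None
) -> None:
    """TSV matrix plus sidecar JSON manifest (name -> group)."""
    import json
    from pathlib import Path

    path = Path(path)
    matrix.to_csv(path, sep="\t")
    mpath = Path(manifest_path) if manifest_path else path.with_suffix(".manifest.json")
    mpath.write_text(json.dumps({k: v.value for k, v in manifest.items()}, indent=0))
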