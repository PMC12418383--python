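"""Average bioluminescence intensity (ABI) from replicate reporter plates.

Each 5'UTR drives a firefly-luciferase reporter measured on (by default)
three independent replicate plates; every plate carries a reference well.
Technical duplicate reads are averaged first, each sample is then
normalized to its own plate's reference well, and the ABI is the mean of
the per-plate ratios:

    ABI = (1/n) * sum_i experimental_BI_i / reference_BI_i.

Per-plate normalization makes the ABI invariant to plate-wide scale
differences (cell density, reagent batch), which is the entire point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ["plate_id", "well", "sample_id", "technical_rep", "signal", "is_reference"]


@dataclass(frozen=True)
class ABIResult:
    sample_id: str
    abi: float
    per_plate_ratios: tuple[float, ...]
    n_plates: int


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Long-format TSV with columns plate_id, well, sample_id, technical_rep, signal, is_reference."""
    table = pd.read_csv(path, sep="\t")
    missing = set(PLATE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def aggregate_technical(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean signal per (plate, sample) over technical replicates."""
    if (measurements["signal"] < 0).any():
        raise ValueError("negative signal in plate table")
    agg = (
        measurements.groupby(["plate_id", "sample_id"], sort=False)
        .agg(signal=("signal", "mean"), is_reference=("is_reference", "max"))
        .reset_index()
    )
    return agg


def compute_abi(
    measurements: pd.DataFrame, n_required_plates: int = 3
) -> dict[str, ABIResult]:
    """ABI per sample: mean over plates of the plate-reference-normalized signal.

    Plates missing a sample reduce that sample's n (logged), rather than
    failing the run; a plate without exactly one reference sample, or with
    a zero reference signal, is an error.
    """
    agg = aggregate_technical(measurements)
    results: dict[str, ABIResult] = {}
    ref_by_plate: dict[str, float] = {}
    for plate_id, plate in agg.groupby("plate_id", sort=False):
        refs = plate[plate["is_reference"].astype(bool)]
        if len(refs) != 1:
            raise ValueError(
                f"plate {plate_id!r}: expected exactly one reference sample, got {len(refs)}"
            )
        ref_signal = float(refs["signal"].iloc[0])
        if ref_signal <= 0:
            raise ValueError(f"plate {plate_id!r}: reference signal is {ref_signal}")
        ref_by_plate[str(plate_id)] = ref_signal

    for sample_id, rows in agg.groupby("sample_id", sort=False):
        ratios = tuple(
            float(row.signal) / ref_by_plate[str(row.plate_id)]
            for row in rows.itertuples()
        )
        if not ratios:
            raise ValueError(f"sample {sample_id!r} appears on no plate")
        if len(ratios) != n_required_plates:
            logger.warning(
                "sample %r measured on %d plates (expected %d)",
                sample_id,
                len(ratios),
                n_required_plates,
            )
        results[str(sample_id)] = ABIResult(
            sample_id=str(sample_id),
            abi=float(np.mean(ratios)),
            per_plate_ratios=ratios,
            n_plates=len(ratios),
        )
    return results


def abi_table(results: dict[str, ABIResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": list(results),
            "abi": [r.abi for r in results.values()],
            "n_plates": [r.n_plates for r in results.values()],
        }
    )
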