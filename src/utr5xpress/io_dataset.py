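"""Reading, writing and filtering of 5'UTR datasets.

A dataset couples 5'UTR sequences (FASTA) with per-sequence annotations
(delimited table: translation-efficiency label on a log scale, transcript
abundance as RPKM, cell line of origin).  This module is the single source
of truth for record semantics: sequence normalization (U->T, upper case),
missingness of labels, and the abundance filter applied before modeling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,U}."""


@dataclass
class UTRRecord:
    """One 5'UTR with its expression annotations.

    ``te_value`` is a translation-efficiency label on a log scale (negative
    values are legitimate); ``rpkm`` is the transcript abundance used for
    quality filtering.  Both are ``None`` when unannotated.
    """

    id: str
    sequence: str
    te_value: float | None = None
    rpkm: float | None = None
    cell_line: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )
        if self.rpkm is not None and self.rpkm < 0:
            raise ValueError(f"record {self.id!r}: negative RPKM {self.rpkm}")


@dataclass
class Dataset:
    """Ordered collection of :class:`UTRRecord` with unique ids."""

    records: list[UTRRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate record id {dup!r} in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[UTRRecord]:
        return iter(self.records)

    def __getitem__(self, key: str) -> UTRRecord:
        for r in self.records:
            if r.id == key:
                return r
        raise KeyError(key)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def te_values(self) -> list[float | None]:
        return [r.te_value for r in self.records]

    def subset(self, ids: Iterable[str], provenance: str | None = None) -> "Dataset":
        """Records with the given ids, in dataset order."""
        wanted = set(ids)
        missing = wanted - set(self.ids())
        if missing:
            raise KeyError(f"ids not in dataset: {sorted(missing)[:5]}")
        recs = [r for r in self.records if r.id in wanted]
        return Dataset(recs, provenance or f"{self.provenance} | subset n={len(recs)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids(),
                "sequence": self.sequences(),
                "te": [r.te_value for r in self.records],
                "rpkm": [r.rpkm for r in self.records],
                "cell_line": [r.cell_line for r in self.records],
            }
        )


def normalize_sequence(raw: str) -> str:
    """Upper-case and map U->T so downstream code sees one DNA alphabet."""
    return raw.upper().replace("U", "T")


def read_fasta(
    path: str | Path,
    invalid: Literal["reject", "drop"] = "reject",
) -> Dataset:
    """Read a multi-FASTA file into a :class:`Dataset`.

    The header token before the first whitespace becomes the record id.
    Sequences are normalized (upper case, U->T).  Records containing other
    characters (ambiguity codes such as N) either raise
    :class:`SequenceValidationError` (``invalid="reject"``, default) or are
    dropped with a logged warning (``invalid="drop"``).
    """
    path = Path(path)
    records: list[UTRRecord] = []
    dropped = 0
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - Bio raises rarely here
        raise FastaParseError(f"{path}: {exc}") from exc
    if not parsed:
        # SeqIO silently yields nothing for a non-FASTA text file
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip():
                    if not line.startswith(">"):
                        raise FastaParseError(
                            f"{path}:{lineno}: expected '>' header, got {line.strip()[:30]!r}"
                        )
                    break
    for entry in parsed:
        seq = normalize_sequence(str(entry.seq))
        bad = set(seq) - _VALID_BASES
        if bad:
            if invalid == "drop":
                dropped += 1
                logger.warning(
                    "dropping record %r: invalid characters %s", entry.id, sorted(bad)
                )
                continue
            raise SequenceValidationError(
                f"record {entry.id!r}: invalid characters {sorted(bad)}"
            )
        records.append(UTRRecord(id=entry.id, sequence=seq))
    prov = f"read_fasta({path.name})"
    if dropped:
        prov += f" [dropped {dropped} invalid records]"
    return Dataset(records, provenance=prov)


def write_fasta(dataset: Dataset, path: str | Path, width: int = 60) -> None:
    """Write sequences as wrapped multi-FASTA (round-trips with read_fasta)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in dataset]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_annotation_table(
    path: str | Path,
    dataset: Dataset,
    id_col: str = "id",
    te_col: str = "te",
    rpkm_col: str = "rpkm",
    cell_line_col: str = "cell_line",
) -> Dataset:
    """Join TE / RPKM / cell-line annotations onto a dataset by exact id.

    The table must be TSV or CSV (sniffed from the extension, ``.csv`` ->
    comma, otherwise tab) with a header row.  Empty cells stay missing
    (``None``), never 0.  Table rows whose id is absent from the dataset are
    reported with a warning; duplicate ids in the table are an error.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype={0: str})
    if id_col not in table.columns:
        raise ValueError(f"{path}: missing id column {id_col!r}")
    table[id_col] = table[id_col].astype(str)
    if table[id_col].duplicated().any():
        dups = table.loc[table[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"{path}: duplicate ids in table: {dups[:5]}")
    by_id = table.set_index(id_col)
    known = set(dataset.ids())
    unmatched = [i for i in by_id.index if i not in known]
    if unmatched:
        logger.warning(
            "%d annotation rows have no matching FASTA record (e.g. %s)",
            len(unmatched),
            unmatched[:3],
        )

    def _get(row: pd.Series, col: str) -> float | None:
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    new_records = []
    for rec in dataset:
        if rec.id in by_id.index:
            row = by_id.loc[rec.id]
            cell = None
            if cell_line_col in row and not pd.isna(row[cell_line_col]):
                cell = str(row[cell_line_col])
            rec = replace(
                rec,
                te_value=_get(row, te_col),
                rpkm=_get(row, rpkm_col),
                cell_line=cell,
            )
        new_records.append(rec)
    return Dataset(
        new_records, provenance=f"{dataset.provenance} + annotations({path.name})"
    )


def filter_dataset(dataset: Dataset, rpkm_min: float = 10.0) -> Dataset:
    """Keep records with a TE label present and RPKM strictly above ``rpkm_min``.

    Low-abundance transcripts (RPKM <= 10 by default) carry noisy TE
    estimates, so they are excluded before training; records with no TE
    label cannot supervise a model and are removed regardless of abundance.
    Idempotent; surviving records are untouched.
    """
    survivors = []
    n_missing_te = n_low_rpkm = 0
    for rec in dataset:
        if rec.te_value is None or (
            isinstance(rec.te_value, float) and math.isnan(rec.te_value)
        ):
            n_missing_te += 1
            continue
        if rec.rpkm is None or not rec.rpkm > rpkm_min:
            n_low_rpkm += 1
            continue
        survivors.append(rec)
    prov = (
        f"{dataset.provenance} | filtered(te present, rpkm>{rpkm_min:g}): "
        f"removed {n_missing_te} missing-TE, {n_low_rpkm} low-RPKM; kept {len(survivors)}"
    )
    return Dataset(survivors, provenance=prov)
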