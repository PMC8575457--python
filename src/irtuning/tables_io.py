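"""Reading and writing sensillum x odor response tables.

Responses are solvent-corrected firing rates (spikes/s) recorded from single
antennal coeloconic sensilla. Tables have one header row of odor names, a
genotype/species label in the first column, an optional ``sensillum`` id
column, and the literal ``NaN`` for cells where the recording was lost (for
example the electrode coming out of the sensillum before the end of the
stimulus series). Missing cells stay missing — they are never silently zero.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: tokens treated as a missing cell (case-insensitive for "nan")
_MISSING_TOKENS = {"", "nan"}

#: default solvents: carboxylic acids in water, diagnostics in paraffin oil
_DEFAULT_ODORS = ("C1", "C2", "C3", "C4", "C5", "C6", "pyridine", "octanol")
_DEFAULT_SOLVENTS = {
    "C1": "water",
    "C2": "water",
    "C3": "water",
    "C4": "water",
    "C5": "water",
    "C6": "water",
    "pyridine": "paraffin oil",
    "octanol": "paraffin oil",
}


class TableFormatError(ValueError):
    """Raised when a response table violates the expected layout."""


@dataclass(frozen=True)
class OdorPanel:
    """Ordered odor set with the solvent used to dilute each odor.

    C1..C6 are the linear carboxylic acids with one to six carbons
    (C2 = acetic acid, C4 = butyric acid). Acids are diluted in water;
    the diagnostic odors pyridine and octanol in paraffin oil.
    """

    odors: tuple[str, ...] = _DEFAULT_ODORS
    solvent_map: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_SOLVENTS))

    def __post_init__(self) -> None:
        if len(set(self.odors)) != len(self.odors):
            raise ValueError("odor identifiers must be unique")
        missing = [o for o in self.odors if o not in self.solvent_map]
        if missing:
            raise ValueError(f"odors without a solvent assignment: {missing}")

    def solvent_of(self, odor: str) -> str:
        try:
            return self.solvent_map[odor]
        except KeyError:
            raise KeyError(f"odor {odor!r} is not in the panel") from None

    @classmethod
    def acids_only(cls) -> "OdorPanel":
        """The C1-C6 acid series used for tuning-profile analysis."""
        odors = ("C1", "C2", "C3", "C4", "C5", "C6")
        return cls(odors, {o: "water" for o in odors})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OdorPanel":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(tuple(cfg["odors"]), dict(cfg["solvent_map"]))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump({"odors": list(self.odors), "solvent_map": dict(self.solvent_map)}, fh)
        return path


@dataclass
class ResponseMatrix:
    """Sensilla x odors table of solvent-corrected responses (spikes/s).

    ``data`` is indexed by a unique per-row id, columns are odors, and
    ``NaN`` marks a missing recording. ``labels`` maps each row id to its
    genotype or species label; ``sensilla`` to the sensillum id within that
    label.
    """

    data: pd.DataFrame
    labels: pd.Series
    sensilla: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("row ids must be unique")
        if not (self.labels.index.equals(self.data.index) and self.sensilla.index.equals(self.data.index)):
            raise ValueError("labels/sensilla must be aligned with data rows")
        values = self.data.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValueError("response values must be finite where present")

    @classmethod
    def from_records(
        cls,
        labels: Sequence[str],
        values: pd.DataFrame | np.ndarray,
        odors: Sequence[str] | None = None,
        sensilla: Sequence[str] | None = None,
    ) -> "ResponseMatrix":
        """Build a matrix from per-row labels and a values array."""
        if isinstance(values, pd.DataFrame):
            frame = values.reset_index(drop=True).astype(float)
        else:
            frame = pd.DataFrame(np.asarray(values, dtype=float), columns=list(odors or []))
        if odors is not None:
            frame.columns = list(odors)
        labels = list(labels)
        if len(labels) != len(frame):
            raise ValueError("one label per row required")
        if sensilla is None:
            counter: dict[str, int] = {}
            sensilla = []
            for lab in labels:
                counter[lab] = counter.get(lab, 0) + 1
                sensilla.append(f"s{counter[lab]}")
        sensilla = list(sensilla)
        row_ids = _unique_row_ids(labels, sensilla)
        frame.index = pd.Index(row_ids, name="row")
        return cls(
            data=frame,
            labels=pd.Series(labels, index=frame.index, name="label"),
            sensilla=pd.Series(sensilla, index=frame.index, name="sensillum"),
        )

    @property
    def odors(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def rows_for(self, label: str) -> pd.DataFrame:
        """All sensillum rows recorded for one genotype/species label."""
        return self.data.loc[self.labels == label]

    def label_counts(self) -> pd.Series:
        return self.labels.value_counts()

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(self.data.copy(), self.labels.copy(), self.sensilla.copy())


def _unique_row_ids(labels: Sequence[str], sensilla: Sequence[str]) -> list[str]:
    """(sensillum id, label) is row identity; duplicates get a numeric suffix."""
    seen: dict[tuple[str, str], int] = {}
    row_ids = []
    for lab, sens in zip(labels, sensilla):
        key = (lab, sens)
        seen[key] = seen.get(key, 0) + 1
        rid = f"{lab}::{sens}"
        if seen[key] > 1:
            rid = f"{rid}#{seen[key]}"
            logger.warning("duplicate (sensillum, label) pair %s; using row id %s", key, rid)
        row_ids.append(rid)
    return row_ids


def _detect_delimiter(header_line: str) -> str:
    """Auto-detect comma vs tab from the header line (spreadsheet exports vary)."""
    return "\t" if header_line.count("\t") >= header_line.count(",") and "\t" in header_line else ","


def _parse_cell(token: str, row: str, column: str) -> float:
    token = token.strip()
    if token.lower() in _MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise TableFormatError(
            f"non-numeric cell {token!r} at row {row!r}, column {column!r}"
        ) from None


def read_response_table(path: str | Path, panel: OdorPanel) -> ResponseMatrix:
    """Read a response table in the source-data CSV/TSV dialect.

    The first column holds the genotype/species label; a column literally
    named ``sensillum`` (any position) is used as the sensillum id; every
    other column must name an odor in ``panel``. Cells that are empty or the
    literal ``NaN`` (any case) are flagged missing. Columns are returned in
    panel order.
    """
    path = Path(path)
    raw = path.read_text()
    lines = [ln for ln in raw.splitlines() if ln.strip() != ""]
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    sep = _detect_delimiter(lines[0])
    parsed = list(csv.reader(lines, delimiter=sep))
    header = [h.strip() for h in parsed[0]]
    if len(header) < 2:
        raise TableFormatError(f"{path}: header must contain a label column and at least one odor")
    label_col, rest = header[0], header[1:]
    odor_cols = [c for c in rest if c != "sensillum"]
    unknown = [c for c in odor_cols if c not in panel.odors]
    if unknown:
        raise TableFormatError(f"{path}: unknown odor column(s) {unknown}; panel has {list(panel.odors)}")

    labels: list[str] = []
    sensilla: list[str] = []
    rows: list[dict[str, float]] = []
    for cells in parsed[1:]:
        cells = [c.strip() for c in cells]
        if len(cells) != len(header):
            raise TableFormatError(f"{path}: row {cells[0]!r} has {len(cells)} cells, expected {len(header)}")
        record = dict(zip(header, cells))
        label = record[label_col]
        labels.append(label)
        sensilla.append(record.get("sensillum", ""))
        rows.append({c: _parse_cell(record[c], label, c) for c in odor_cols})

    if any(s == "" for s in sensilla):
        counter: dict[str, int] = {}
        filled = []
        for lab, s in zip(labels, sensilla):
            if s == "":
                counter[lab] = counter.get(lab, 0) + 1
                s = f"s{counter[lab]}"
            filled.append(s)
        sensilla = filled

    ordered = [o for o in panel.odors if o in odor_cols]
    frame = pd.DataFrame(rows, columns=ordered, dtype=float)
    return ResponseMatrix.from_records(labels, frame, odors=ordered, sensilla=sensilla)


def write_response_table(matrix: ResponseMatrix, path: str | Path, sep: str = ",") -> Path:
    """Write a matrix so that :func:`read_response_table` inverts it exactly.

    Missing cells are written as the literal ``NaN``; present values use
    Python repr, which round-trips float64 bit-exactly.
    """
    path = Path(path)
    out = pd.DataFrame(
        {"label": matrix.labels.to_numpy(), "sensillum": matrix.sensilla.to_numpy()},
    )
    for odor in matrix.odors:
        out[odor] = [("NaN" if pd.isna(v) else repr(float(v))) for v in matrix.data[odor]]
    out.to_csv(path, sep=sep, index=False, na_rep="NaN")
    return path
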