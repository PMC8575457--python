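"""Spike-train quantification and per-sensillum response transforms.

A response is the number of spikes in a 500 ms window at stimulus delivery
(delivery lags odor-valve opening by ~200 ms of air path), minus the count in
a 500 ms window 2 s before delivery, doubled to give spikes/s. All OSNs in a
sensillum are summed; no spike sorting. Solvent correction subtracts the
response to the bare solvent, per sensillum. Downstream analyses use either
max-normalized rows (each sensillum scaled by its own peak response) or
z-scored rows (per-sensillum mean 0, sample SD 1 across odors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from irtuning.tables_io import OdorPanel, ResponseMatrix

logger = logging.getLogger(__name__)


class WindowError(ValueError):
    """Counting window extends beyond the recorded span."""


class SolventMismatchError(ValueError):
    """Solvent response does not match the odor's assigned solvent."""


class NonNormalizableRowError(ValueError):
    """Row has no positive response to scale by."""


class ZeroVarianceError(ValueError):
    """Row is constant; z-scoring undefined."""


@dataclass
class SpikeTrain:
    """Spike times for one trial plus stimulus timing.

    Times are seconds from the start of the recording. ``delivery_delay``
    is the lag between valve opening (``stimulus_onset``) and odor arrival
    at the antenna. ``baseline_offset`` anchors the baseline window this
    many seconds before *delivery*.
    """

    spike_times: np.ndarray
    stimulus_onset: float
    delivery_delay: float = 0.2
    window: float = 0.5
    baseline_offset: float = 2.0
    recording_span: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be sorted ascending")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError("spike_times must be non-negative")
        if self.window <= 0:
            raise ValueError("window must be positive")

    @property
    def delivery(self) -> float:
        return self.stimulus_onset + self.delivery_delay


@dataclass(frozen=True)
class RawResponse:
    """Background-subtracted firing-rate response, spikes/s.

    Equal to 2 x (stimulus-window count - baseline-window count) for the
    standard 500 ms windows, hence an even integer and possibly negative
    (odor-evoked suppression). ``stimulus`` names the odor, or the solvent
    for blank presentations.
    """

    value: float
    stimulus: str | None = None


def _count_halfopen(times: np.ndarray, start: float, end: float) -> int:
    """Spikes in [start, end); boundary spikes belong to the window they start."""
    return int(np.searchsorted(times, end, side="left") - np.searchsorted(times, start, side="left"))


def count_response(train: SpikeTrain, stimulus: str | None = None) -> RawResponse:
    """Background-subtracted response of one trial in spikes/s.

    Counts spikes in the 500 ms (``train.window``) stimulus window starting
    at odor delivery and in an equal baseline window ``baseline_offset``
    seconds earlier, and doubles the difference to convert the half-second
    counts to a rate.
    """
    stim_start = train.delivery
    base_start = train.delivery - train.baseline_offset
    span_end = train.recording_span
    for name, start in (("baseline", base_start), ("stimulus", stim_start)):
        end = start + train.window
        if start < 0 or (span_end is not None and end > span_end):
            raise WindowError(
                f"{name} window [{start:.3f}, {end:.3f}) outside recorded span "
                f"[0, {span_end if span_end is not None else 'inf'})"
            )
    n_stim = _count_halfopen(train.spike_times, stim_start, stim_start + train.window)
    n_base = _count_halfopen(train.spike_times, base_start, base_start + train.window)
    return RawResponse(value=2.0 * (n_stim - n_base), stimulus=stimulus)


def solvent_correct(
    odor_response: RawResponse,
    solvent_response: RawResponse,
    panel: OdorPanel | None = None,
) -> float:
    """Odor response minus same-sensillum solvent response, spikes/s.

    If a panel is given, the solvent presentation must match the odor's
    assigned solvent. A missing odor response propagates as missing.
    """
    if panel is not None and odor_response.stimulus is not None:
        expected = panel.solvent_of(odor_response.stimulus)
        if solvent_response.stimulus is not None and solvent_response.stimulus != expected:
            raise SolventMismatchError(
                f"odor {odor_response.stimulus!r} requires solvent {expected!r}, "
                f"got {solvent_response.stimulus!r}"
            )
    if np.isnan(odor_response.value) or np.isnan(solvent_response.value):
        return float("nan")
    return float(odor_response.value - solvent_response.value)


def normalize_max(row: pd.Series) -> pd.Series:
    """Scale a sensillum's responses by its maximal response.

    After scaling, the non-missing maximum is exactly 1 (ties all map to 1).
    Rows whose responses are all missing or all <= 0 cannot be normalized.
    """
    values = row.astype(float)
    present = values.dropna()
    if present.empty or present.max() <= 0:
        raise NonNormalizableRowError(f"row {row.name!r}: no positive response to normalize by")
    return values / present.max()


def zscore_row(row: pd.Series) -> pd.Series:
    """Per-sensillum z-score across odors: mean 0, sample SD 1 (N-1 denominator).

    Missing cells are excluded from the mean/SD and stay missing.
    """
    values = row.astype(float)
    present = values.dropna()
    if len(present) < 2:
        raise ZeroVarianceError(f"row {row.name!r}: need >=2 non-missing values to z-score")
    sd = present.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError(f"row {row.name!r}: zero variance, z-score undefined")
    return (values - present.mean()) / sd


def normalize_matrix(matrix: ResponseMatrix) -> ResponseMatrix:
    """Max-normalize every row; non-normalizable rows are dropped with a warning."""
    kept_rows, kept_idx = [], []
    for rid, row in matrix.data.iterrows():
        try:
            kept_rows.append(normalize_max(row))
            kept_idx.append(rid)
        except NonNormalizableRowError as err:
            logger.warning("excluding row: %s", err)
    data = pd.DataFrame(kept_rows, index=pd.Index(kept_idx, name="row"))
    return ResponseMatrix(data, matrix.labels.loc[kept_idx], matrix.sensilla.loc[kept_idx])


def zscore_matrix(matrix: ResponseMatrix) -> ResponseMatrix:
    """Z-score every row (per sensillum, across odors)."""
    data = pd.DataFrame(
        [zscore_row(row) for _, row in matrix.data.iterrows()], index=matrix.data.index
    )
    return ResponseMatrix(data, matrix.labels.copy(), matrix.sensilla.copy())


def read_spike_times(path, trial_column: str = "trial", time_column: str = "time") -> dict[str, np.ndarray]:
    """Read per-trial spike times from a two-column CSV (trial id, time in s)."""
    frame = pd.read_csv(path)
    if trial_column not in frame.columns or time_column not in frame.columns:
        raise ValueError(f"spike CSV must have columns {trial_column!r} and {time_column!r}")
    return {
        str(trial): np.sort(group[time_column].to_numpy(dtype=float))
        for trial, group in frame.groupby(trial_column, sort=True)
    }
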