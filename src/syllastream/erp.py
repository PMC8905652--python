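"""ERP preprocessing and measurement.

The pipeline mirrors standard ERP practice for word-onset-locked analyses
of a continuous familiarization stream: re-reference to the algebraic
mastoid average, zero-phase Butterworth band-pass (0.1-30 Hz), epoch from
-300 to 1,200 ms around word onsets with baseline correction over
-300..0 ms, reject epochs whose amplitude exceeds +-100 uV on any channel,
apply a two-thirds per-condition retention rule for participant inclusion,
average by condition, and extract mean amplitudes over named electrode
regions (ROIs) and component time windows.

All window bounds are inclusive at sample resolution; 0 ms is the word
onset sample.  The +-100 uV criterion is a strict inequality on
baseline-corrected values.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger(__name__)

__all__ = [
    "ContinuousEEG",
    "EpochSet",
    "RoiSpec",
    "CANONICAL_ROIS",
    "COMPONENT_WINDOWS",
    "DEFAULT_MONTAGE",
    "rereference_mastoids",
    "bandpass",
    "epoch",
    "apply_baseline",
    "reject_artifacts",
    "include_participant",
    "condition_erps",
    "roi_window_mean",
    "build_erp_table",
]

#: Scalp channels covering every canonical ROI, plus the two mastoids.
DEFAULT_MONTAGE = [
    "AF3", "AFz", "AF4",
    "F1", "Fz", "F2",
    "FC1", "FCz", "FC2",
    "C1", "Cz", "C2",
    "CP1", "CPz", "CP2",
    "M1", "M2",
]

CONDITION_COLUMNS = ("task", "tp_class", "half")


@dataclass
class ContinuousEEG:
    """A continuous multichannel recording in microvolts."""

    ch_names: list[str]
    sfreq: float
    data: np.ndarray  # (n_channels, n_samples), uV
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError("data must be (n_channels, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "ContinuousEEG":
        return ContinuousEEG(list(self.ch_names), self.sfreq,
                             self.data.copy(), self.units)

    def pick(self, channels: Sequence[str]) -> np.ndarray:
        idx = []
        for ch in channels:
            if ch not in self.ch_names:
                raise KeyError(f"channel {ch!r} not in recording")
            idx.append(self.ch_names.index(ch))
        return self.data[idx]

    def save(self, path: str | Path) -> None:
        """Write samples as ``<path>.npz`` with a JSON sidecar ``<path>.json``."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), data=self.data)
        path.with_suffix(".json").write_text(json.dumps(
            {"ch_names": self.ch_names, "sfreq": self.sfreq,
             "units": self.units}))

    @classmethod
    def load(cls, path: str | Path) -> "ContinuousEEG":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))["data"]
        return cls(ch_names=meta["ch_names"], sfreq=meta["sfreq"],
                   data=data, units=meta.get("units", "uV"))

    def to_mne(self):
        """Export to an :class:`mne.io.RawArray` (volts, EEG channel type)."""
        import mne

        info = mne.create_info(self.ch_names, self.sfreq, ch_types="eeg")
        return mne.io.RawArray(self.data * 1e-6, info, verbose="error")


def rereference_mastoids(eeg: ContinuousEEG,
                         mastoids: tuple[str, str] = ("M1", "M2")) -> ContinuousEEG:
    """Subtract the algebraic mastoid average from every channel."""
    for ch in mastoids:
        if ch not in eeg.ch_names:
            raise KeyError(f"mastoid channel {ch!r} missing from recording")
    ref = eeg.pick(mastoids).mean(axis=0)
    out = eeg.copy()
    out.data -= ref[np.newaxis, :]
    return out


def bandpass(eeg: ContinuousEEG, low: float = 0.1, high: float = 30.0,
             order: int = 4) -> ContinuousEEG:
    """Zero-phase (forward-backward) Butterworth band-pass.

    ``order`` is the per-pass filter order; the forward-backward application
    doubles the effective attenuation and cancels the phase response.
    """
    nyq = eeg.sfreq / 2
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz must lie strictly inside (0, {nyq}) Hz")
    sos = butter(order, [low, high], btype="bandpass", fs=eeg.sfreq,
                 output="sos")
    out = eeg.copy()
    out.data = sosfiltfilt(sos, out.data, axis=1)
    return out


@dataclass
class EpochSet:
    """Word-onset-locked epochs for one participant.

    ``data`` is (epochs, channels, samples); ``labels`` carries one row per
    epoch (task, tp_class, block, half, ...); ``retained`` is the running
    inclusion mask updated by artifact rejection.
    """

    data: np.ndarray
    labels: pd.DataFrame
    times_ms: np.ndarray
    ch_names: list[str]
    sfreq: float
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = np.ones(len(self.data), dtype=bool)

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.labels.copy(),
                        self.times_ms.copy(), list(self.ch_names),
                        self.sfreq, self.retained.copy())


def epoch(eeg: ContinuousEEG, events: pd.DataFrame,
          window_ms: tuple[float, float] = (-300.0, 1200.0),
          baseline_ms: tuple[float, float] | None = (-300.0, 0.0),
          label_columns: Sequence[str] | None = None) -> EpochSet:
    """Cut word-onset epochs out of a continuous recording.

    ``events`` needs an ``onset_ms`` column; label columns (``task``,
    ``tp_class``, ``block``, ``half``, ...) are carried onto the epochs.
    Events without full pre/post context are dropped with a logged warning.
    Baseline correction subtracts the per-channel mean over ``baseline_ms``
    (inclusive bounds at sample resolution); pass ``None`` to skip it and
    apply it later with :func:`apply_baseline`.
    """
    sfreq = eeg.sfreq
    start_off = round(window_ms[0] / 1000 * sfreq)
    n_samp = round((window_ms[1] - window_ms[0]) / 1000 * sfreq)
    times_ms = (start_off + np.arange(n_samp)) / sfreq * 1000

    if label_columns is None:
        label_columns = [c for c in events.columns
                         if c not in ("onset_ms", "duration_ms")]

    chunks, labels = [], []
    n_dropped = 0
    for row in events.itertuples():
        onset_sample = round(row.onset_ms / 1000 * sfreq)
        lo = onset_sample + start_off
        hi = lo + n_samp
        if lo < 0 or hi > eeg.n_samples:
            n_dropped += 1
            continue
        chunks.append(eeg.data[:, lo:hi])
        labels.append({c: getattr(row, c) for c in label_columns})
    if n_dropped:
        logger.warning("dropped %d event(s) too close to the record edge",
                       n_dropped)
    if not chunks:
        raise ValueError("no event had full epoch context")

    out = EpochSet(data=np.stack(chunks), labels=pd.DataFrame(labels),
                   times_ms=times_ms, ch_names=list(eeg.ch_names), sfreq=sfreq)
    if baseline_ms is not None:
        out = apply_baseline(out, baseline_ms)
    return out


def apply_baseline(epochs: EpochSet,
                   baseline_ms: tuple[float, float] = (-300.0, 0.0)) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    mask = (epochs.times_ms >= baseline_ms[0]) & (epochs.times_ms <= baseline_ms[1])
    if not mask.any():
        raise ValueError(f"baseline window {baseline_ms} contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 100.0,
                     channels: Sequence[str] | None = None) -> EpochSet:
    """Reject epochs whose amplitude strictly exceeds ``threshold_uv`` on any
    (scalp) channel at any sample; the retained mask is ANDed in place of a
    copy so earlier exclusions persist."""
    out = epochs.copy()
    if channels is None:
        data = out.data
    else:
        idx = [out.ch_names.index(c) for c in channels]
        data = out.data[:, idx, :]
    peak = np.abs(data).max(axis=(1, 2))
    out.retained &= peak <= threshold_uv
    return out


def include_participant(epochs: EpochSet, min_fraction: float = 2 / 3,
                        cells: Sequence[str] = CONDITION_COLUMNS) -> bool:
    """Two-thirds rule: keep the participant only if every condition cell
    retains at least ``ceil(min_fraction * cell size)`` epochs."""
    cells = [c for c in cells if c in epochs.labels.columns]
    grouped = epochs.labels.groupby(list(cells), observed=True)
    for key, idx in grouped.groups.items():
        total = len(idx)
        if total == 0:
            logger.info("participant excluded: empty condition cell %s", key)
            return False
        kept = int(epochs.retained[np.asarray(idx)].sum())
        if kept < math.ceil(min_fraction * total):
            logger.info("participant excluded: cell %s retains %d/%d",
                        key, kept, total)
            return False
    return True


def condition_erps(epochs: EpochSet,
                   by: Sequence[str] = CONDITION_COLUMNS
                   ) -> dict[tuple, np.ndarray]:
    """Sample-wise mean over retained epochs per condition cell.

    Returns ``{condition tuple: (channels, samples) array}``; an empty cell
    yields an all-NaN array.
    """
    by = [c for c in by if c in epochs.labels.columns]
    out: dict[tuple, np.ndarray] = {}
    for key, idx in epochs.labels.groupby(list(by), observed=True).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        sel = np.asarray(idx)[epochs.retained[np.asarray(idx)]]
        if len(sel) == 0:
            out[key] = np.full(epochs.data.shape[1:], np.nan)
        else:
            out[key] = epochs.data[sel].mean(axis=0)
    return out


@dataclass(frozen=True)
class RoiSpec:
    """A named electrode region with a component measurement window (ms)."""

    name: str
    channels: tuple[str, ...]
    window_ms: tuple[float, float]


#: Canonical electrode regions.
CANONICAL_ROIS: dict[str, tuple[str, ...]] = {
    "fronto_central": ("F1", "Fz", "F2", "FC1", "FCz", "FC2", "C1", "Cz", "C2"),
    "frontal": ("AF3", "AFz", "AF4", "F1", "Fz", "F2", "FC1", "FCz", "FC2"),
    "central": ("FC1", "FCz", "FC2", "C1", "Cz", "C2", "CP1", "CPz", "CP2"),
}

#: Component measurement windows (ms) per group: N100 is shared; the N400
#: window is 50 ms later in children, tracking its delayed latency.
COMPONENT_WINDOWS: dict[str, dict[str, tuple[float, float]]] = {
    "adults": {"N100": (80.0, 120.0), "N400": (350.0, 450.0)},
    "children": {"N100": (80.0, 120.0), "N400": (400.0, 500.0)},
}


def roi_window_mean(erp: np.ndarray, times_ms: np.ndarray,
                    ch_names: Sequence[str], roi: RoiSpec) -> float:
    """Mean amplitude over the ROI channels and window samples (inclusive)."""
    missing = [c for c in roi.channels if c not in ch_names]
    if missing:
        raise KeyError(f"ROI {roi.name!r}: missing electrode(s) {missing}")
    idx = [list(ch_names).index(c) for c in roi.channels]
    tmask = (times_ms >= roi.window_ms[0]) & (times_ms <= roi.window_ms[1])
    if not tmask.any():
        raise ValueError(f"window {roi.window_ms} contains no samples")
    return float(erp[np.ix_(idx, np.flatnonzero(tmask))].mean())


def build_erp_table(subject_epochs: Mapping[str, EpochSet],
                    rois: Mapping[str, RoiSpec],
                    by: Sequence[str] = CONDITION_COLUMNS) -> pd.DataFrame:
    """Participant x condition x component mean-amplitude table.

    ``rois`` maps component name (e.g. ``"N400"``) to its
    :class:`RoiSpec`.  Rows: subject, condition labels, component,
    amplitude (uV).
    """
    rows = []
    for subject, epochs in subject_epochs.items():
        erps = condition_erps(epochs, by=by)
        used_by = [c for c in by if c in epochs.labels.columns]
        for key, wave in erps.items():
            for component, roi in rois.items():
                rows.append({
                    "subject": subject,
                    **dict(zip(used_by, key)),
                    "component": component,
                    "roi": roi.name,
                    "amplitude": roi_window_mean(wave, epochs.times_ms,
                                                 epochs.ch_names, roi),
                })
    return pd.DataFrame(rows)
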