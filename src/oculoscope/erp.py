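"""Epoching, averaging, latency binning, and saccade-locked re-alignment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Epochs",
    "ERP",
    "epoch",
    "baseline_correct",
    "average",
    "bin_by_saccade_latency",
    "realign_to_saccade",
    "component_latency",
    "window_mean",
]


@dataclass
class Epochs:
    """Trials x channels x time array with alignment metadata.

    ``times`` is shared by all trials; ``alignment`` is ``"stimulus"`` or
    ``"saccade_k"``; ``meta`` carries one row per trial (condition, trial_id,
    first_saccade_latency, bin_index ... as available).
    """

    data: np.ndarray
    times: np.ndarray
    sample_rate: float
    channels: list
    alignment: str = "stimulus"
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis mismatch")
        if len(self.meta) and len(self.meta) != self.data.shape[0]:
            raise ValueError("meta row count must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    def select_trials(self, mask) -> "Epochs":
        mask = np.asarray(mask)
        meta = self.meta.iloc[mask].reset_index(drop=True) if len(self.meta) else self.meta
        return replace(self, data=self.data[mask], meta=meta)

    def copy(self) -> "Epochs":
        return replace(self, data=self.data.copy(), meta=self.meta.copy())


@dataclass
class ERP:
    """Trial-average with SEM and provenance."""

    mean: np.ndarray  # channels x time
    sem: np.ndarray
    times: np.ndarray
    channels: list
    n_trials: int
    alignment: str = "stimulus"
    group: str | None = None

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be > 0")

    def trace(self, channel=None) -> np.ndarray:
        if channel is None:
            return self.mean.mean(axis=0)
        return self.mean[self.channels.index(channel)]


class EmptyEpochsError(ValueError):
    pass


def epoch(recording, onsets, window, alignment="stimulus", meta=None,
          channels=None) -> Epochs:
    """Cut sample-accurate epochs around ``onsets`` (seconds on the recording
    clock).  Time 0 of each epoch coincides with the sample nearest the onset.
    Epochs overlapping the recording edges are dropped (and reported via the
    returned meta ``kept`` ordering).
    """
    data = np.asarray(recording.data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    sr = float(recording.sample_rate)
    i_lo = int(round(window[0] * sr))
    i_hi = int(round(window[1] * sr))
    if i_hi <= i_lo:
        raise ValueError("empty epoch window")
    n_time = data.shape[1]
    segs, kept = [], []
    for j, onset in enumerate(np.atleast_1d(onsets)):
        c = int(round(onset * sr))
        if c + i_lo < 0 or c + i_hi > n_time:
            continue
        segs.append(data[:, c + i_lo : c + i_hi])
        kept.append(j)
    if not segs:
        raise EmptyEpochsError("no epoch fits inside the recording")
    if len(kept) < np.atleast_1d(onsets).size:
        warnings.warn(f"dropped {np.atleast_1d(onsets).size - len(kept)} edge-overlapping trials")
    times = np.arange(i_lo, i_hi) / sr
    if meta is not None:
        meta = meta.iloc[kept].reset_index(drop=True)
    else:
        meta = pd.DataFrame({"trial_id": kept})
    labels = channels if channels is not None else list(getattr(recording, "labels", []) or
                                                        [f"ch{i}" for i in range(data.shape[0])])
    return Epochs(
        data=np.asarray(segs),
        times=times,
        sample_rate=sr,
        channels=labels,
        alignment=alignment,
        meta=meta,
    )


def baseline_correct(epochs: Epochs, window=(-0.170, 0.0)) -> Epochs:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    t0 = max(window[0], epochs.times[0])
    t1 = window[1]
    sel = (epochs.times >= t0) & (epochs.times < t1)
    if not sel.any():
        raise ValueError("baseline window outside epoch")
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    out = epochs.copy()
    out.data = epochs.data - base
    return out


def average(epochs: Epochs, by: str | None = None, min_n: int = 2):
    """Mean/SEM over trials.  With ``by``, returns ``{label: ERP}`` grouped on
    a meta column; empty groups are dropped with a warning, small groups are
    kept but flagged via ``warnings``."""
    if by is None:
        return _erp_of(epochs.data, epochs, group=None)
    if by not in epochs.meta.columns:
        raise KeyError(f"meta column {by!r} missing")
    out = {}
    for label, idx in epochs.meta.groupby(by, sort=True, dropna=True).groups.items():
        sub = epochs.data[np.asarray(idx)]
        if sub.shape[0] == 0:
            warnings.warn(f"group {label!r} empty; dropped")
            continue
        if sub.shape[0] < min_n:
            warnings.warn(f"group {label!r} has n={sub.shape[0]} < {min_n}")
        out[label] = _erp_of(sub, epochs, group=str(label))
    return out


def _erp_of(data: np.ndarray, epochs: Epochs, group) -> ERP:
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    return ERP(
        mean=mean,
        sem=sd / np.sqrt(n),
        times=epochs.times,
        channels=list(epochs.channels),
        n_trials=n,
        alignment=epochs.alignment,
        group=group,
    )


def bin_by_saccade_latency(
    epochs: Epochs,
    n_bins: int = 4,
    window=(0.150, 0.300),
    latency_column: str = "first_saccade_latency",
) -> Epochs:
    """Quantile bins over first-saccade latency within ``[window)``.

    Trials without a saccade in the window are excluded.  Bin occupancies
    differ by at most one (rank split).  Adds a ``bin_index`` meta column
    (0 = earliest).
    """
    lat = epochs.meta[latency_column].to_numpy(dtype=float)
    ok = np.isfinite(lat) & (lat >= window[0]) & (lat < window[1])
    if ok.sum() < n_bins:
        raise ValueError(f"only {int(ok.sum())} trials with in-window saccades; need >= {n_bins}")
    sub = epochs.select_trials(np.flatnonzero(ok))
    lat = lat[ok]
    order = np.argsort(lat, kind="stable")
    bins = np.empty(lat.size, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    sub.meta = sub.meta.assign(bin_index=bins)
    return sub


def realign_to_saccade(epochs: Epochs, saccade_onsets, k: int = 1) -> Epochs:
    """Shift each trial so time 0 is the k-th saccade onset; crop all trials to
    the common overlap window.

    ``saccade_onsets`` is an array of per-trial onset times (seconds, on the
    current epoch clock) for the k-th saccade; pass NaN for trials lacking one
    (those trials are excluded).
    """
    onsets = np.asarray(saccade_onsets, dtype=float)
    if onsets.size != epochs.n_trials:
        raise ValueError("one saccade onset per trial required")
    ok = np.isfinite(onsets)
    if not ok.any():
        raise ValueError("no trial has the requested saccade")
    sub = epochs.select_trials(np.flatnonzero(ok))
    sr = epochs.sample_rate
    t0 = epochs.times[0]
    # sample index of the saccade within each epoch
    sacc_idx = np.round((onsets[ok] - t0) * sr).astype(int)
    n_time = epochs.times.size
    # saccade-relative sample range shared by every trial
    r_lo = -int(sacc_idx.min())
    r_hi = n_time - int(sacc_idx.max())
    if r_hi <= r_lo:
        raise ValueError("empty overlap window after re-alignment")
    out = np.empty((sub.n_trials, sub.data.shape[1], r_hi - r_lo))
    for i, m in enumerate(sacc_idx):
        out[i] = sub.data[i, :, m + r_lo : m + r_hi]
    sub.data = out
    sub.times = np.arange(r_lo, r_hi) / sr
    sub.alignment = f"saccade_{k}"
    return sub


def component_latency(erp, search_window, polarity: str = "negative", channel=None):
    """Latency (s) of the signed extremum inside ``search_window``.

    ``erp`` may be an :class:`ERP` or a 1-D trace paired with times via the
    tuple ``(trace, times)``.  Flat signals resolve to the earliest extremum.
    """
    trace, times = _trace_times(erp, channel)
    sel = (times >= search_window[0]) & (times <= search_window[1])
    if not sel.any():
        raise ValueError("search window outside epoch")
    seg = trace[sel]
    idx = int(np.argmin(seg)) if polarity == "negative" else int(np.argmax(seg))
    return float(times[sel][idx])


def window_mean(erp, window=(0.400, 1.000), channel=None) -> float:
    """Time-average of the trace over ``[window)``."""
    trace, times = _trace_times(erp, channel)
    sel = (times >= window[0]) & (times < window[1])
    if not sel.any():
        raise ValueError("window outside epoch")
    return float(trace[sel].mean())


def _trace_times(erp, channel):
    if isinstance(erp, ERP):
        return erp.trace(channel), erp.times
    trace, times = erp
    return np.asarray(trace, dtype=float), np.asarray(times, dtype=float)
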