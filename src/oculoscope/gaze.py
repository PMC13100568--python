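"""Gaze-derived measures: velocity, density maps, dispersion, saccade events."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter1d

from .tfr import TFRMap

__all__ = [
    "GazeDensityMap",
    "SaccadeEvent",
    "eye_velocity",
    "range_correct",
    "gaze_density",
    "dispersion_raw",
    "gaze_dispersion",
    "detect_saccades",
    "first_saccade_latency",
]


@dataclass
class GazeDensityMap:
    grid: np.ndarray  # (ny, nx)
    x_edges: np.ndarray
    y_edges: np.ndarray
    window: tuple
    smoothing_sigma: float
    n_samples: int

    def as_tfr(self) -> TFRMap:
        """View the map as a TFR-shaped container (x -> time axis, y -> freq
        axis) so cluster statistics can run on it unchanged."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        return TFRMap(power=self.grid[None, None, :, :], freqs=yc, times=xc,
                      channels=["gaze"])


@dataclass
class SaccadeEvent:
    onset: float
    offset: float
    amplitude: float  # px
    direction: float  # radians in (-pi, pi], screen convention (y down)
    peak_velocity: float
    latency: float | None = None  # s from stimulus onset, when applicable


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """NaN-propagating centred moving average.

    The filter runs on a zero-filled copy (scipy's running sum would smear a
    NaN to the end of the array); any window containing a lost sample is then
    marked missing.
    """
    bad = ~np.isfinite(x)
    filled = np.where(bad, 0.0, x)
    out = uniform_filter1d(filled, size=n, mode="nearest")
    if bad.any():
        spread = uniform_filter1d(bad.astype(float), size=n, mode="nearest") > 1e-12
        out[spread] = np.nan
    return out


def eye_velocity(gaze, smooth_window: float = 0.100) -> np.ndarray:
    """Absolute gaze speed (px/s): Euclidean norm of the temporal derivative of
    position smoothed with a ``smooth_window`` moving average.

    Lost samples propagate as NaN.
    """
    sr = gaze.sample_rate
    n = max(int(round(smooth_window * sr)), 2)
    x = np.asarray(gaze.x, dtype=float).copy()
    y = np.asarray(gaze.y, dtype=float).copy()
    lost = np.asarray(gaze.loss_mask, dtype=bool)
    x[lost] = np.nan
    y[lost] = np.nan
    xs = _moving_average(x, n)
    ys = _moving_average(y, n)
    vx = np.gradient(xs) * sr
    vy = np.gradient(ys) * sr
    return np.hypot(vx, vy)


def range_correct(series: np.ndarray) -> np.ndarray:
    """Min-max map of the finite values to [0, 1] (a non-destructive view used
    to juxtapose traces with different native units)."""
    series = np.asarray(series, dtype=float)
    finite = np.isfinite(series)
    if not finite.any():
        return series.copy()
    lo = np.nanmin(series)
    hi = np.nanmax(series)
    if hi == lo:
        out = np.zeros_like(series)
        out[~finite] = np.nan
        return out
    return (series - lo) / (hi - lo)


def gaze_density(
    gaze,
    window: tuple[float, float],
    grid: tuple[int, int] = (1000, 1000),
    sigma: float = 5.0,
) -> GazeDensityMap:
    """2D histogram of gaze samples in ``[window)`` on a fixed screen-spanning
    grid, Gaussian-smoothed with ``sigma`` bins.

    Smoothing uses a reflecting boundary, which conserves total mass exactly.
    """
    t = np.asarray(gaze.time, dtype=float)
    sel = (t >= window[0]) & (t < window[1]) & ~np.asarray(gaze.loss_mask, dtype=bool)
    x = np.asarray(gaze.x, dtype=float)[sel]
    y = np.asarray(gaze.y, dtype=float)[sel]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no usable gaze sample in the requested window")
    w, h = gaze.screen.width_px, gaze.screen.height_px
    x_edges = np.linspace(0, w, grid[0] + 1)
    y_edges = np.linspace(0, h, grid[1] + 1)
    counts, _, _ = np.histogram2d(y, x, bins=(y_edges, x_edges))
    if sigma > 0:
        smoothed = gaussian_filter(counts, sigma=sigma, mode="reflect")
    else:
        smoothed = counts
    return GazeDensityMap(
        grid=smoothed,
        x_edges=x_edges,
        y_edges=y_edges,
        window=window,
        smoothing_sigma=sigma,
        n_samples=int(x.size),
    )


def dispersion_raw(
    x,
    y,
    screen,
    border_margin: float = 0.05,
    jump_reject: float = 0.20,
    loss_mask=None,
):
    """sqrt(var(x) + var(y)) after the exclusion cascade.

    Excluded: lost samples; samples within ``border_margin`` of the screen
    borders; samples whose inter-sample displacement exceeds ``jump_reject`` of
    the screen extent.  Returns ``(value_or_nan, n_excluded_by_cause)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w, h = screen.width_px, screen.height_px
    lost = ~np.isfinite(x) | ~np.isfinite(y)
    if loss_mask is not None:
        lost |= np.asarray(loss_mask, dtype=bool)
    border = (
        (x < border_margin * w)
        | (x > (1 - border_margin) * w)
        | (y < border_margin * h)
        | (y > (1 - border_margin) * h)
    ) & ~lost
    extent = float(np.hypot(w, h))
    disp = np.hypot(np.diff(x), np.diff(y))
    jump = np.zeros_like(lost)
    jump[1:] = disp > jump_reject * extent  # sample following a rejected displacement
    jump &= ~lost
    keep = ~(lost | border | jump)
    counts = {
        "lost": int(lost.sum()),
        "border": int(border.sum()),
        "jump": int(jump.sum()),
    }
    if keep.sum() < 2:
        return np.nan, counts
    value = float(np.sqrt(np.var(x[keep]) + np.var(y[keep])))
    return value, counts


def gaze_dispersion(trials, screen, border_margin: float = 0.05, jump_reject: float = 0.20):
    """Z-scored dispersion across a collection of trials.

    ``trials`` is a sequence of ``(x, y)`` or ``(x, y, loss_mask)`` tuples; the
    z-score is computed over the finite raw values of this collection.
    Returns ``(z_values, raw_values, reports)`` with NaN for dropped trials.
    """
    raw = []
    reports = []
    for tr in trials:
        x, y = tr[0], tr[1]
        lm = tr[2] if len(tr) > 2 else None
        v, counts = dispersion_raw(x, y, screen, border_margin, jump_reject, loss_mask=lm)
        raw.append(v)
        reports.append(counts)
    raw = np.asarray(raw, dtype=float)
    finite = np.isfinite(raw)
    z = np.full_like(raw, np.nan)
    if finite.sum() >= 2:
        mu = raw[finite].mean()
        sd = raw[finite].std(ddof=1)
        if sd > 0:
            z[finite] = (raw[finite] - mu) / sd
        else:
            z[finite] = 0.0
    return z, raw, reports


def detect_saccades(
    velocity,
    gaze,
    baseline_window: tuple[float, float] | None = None,
    threshold: float | None = None,
    mad_factor: float = 6.0,
    min_duration: float = 0.012,
    merge_gap: float = 0.020,
    centroid_window: float = 0.050,
) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detector.

    The default threshold is ``median + mad_factor * MAD`` of the velocity
    within ``baseline_window`` (or the whole trace if None).  Supra-threshold
    runs shorter than ``min_duration`` are discarded; runs separated by less
    than ``merge_gap`` are merged.  Amplitude and direction come from mean
    gaze position in ``centroid_window`` before onset vs after offset.
    """
    v = np.asarray(velocity, dtype=float)
    t = np.asarray(gaze.time, dtype=float)
    sr = gaze.sample_rate
    if threshold is None:
        if baseline_window is not None:
            sel = (t >= baseline_window[0]) & (t < baseline_window[1])
            ref = v[sel]
        else:
            ref = v
        ref = ref[np.isfinite(ref)]
        if ref.size == 0:
            return []
        med = np.median(ref)
        mad = np.median(np.abs(ref - med))
        threshold = med + mad_factor * max(mad, 1e-12)

    above = np.isfinite(v) & (v > threshold)
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    runs = list(zip(starts, ends))
    # merge runs separated by < merge_gap
    merged = [runs[0]]
    gap = int(round(merge_gap * sr))
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    min_len = max(int(round(min_duration * sr)), 1)
    cw = max(int(round(centroid_window * sr)), 1)
    x = np.asarray(gaze.x, dtype=float)
    y = np.asarray(gaze.y, dtype=float)
    events = []
    for s, e in merged:
        if e - s < min_len:
            continue
        pre = slice(max(s - cw, 0), s)
        post = slice(e, min(e + cw, v.size))
        with np.errstate(invalid="ignore"):
            x0, y0 = np.nanmean(x[pre]), np.nanmean(y[pre])
            x1, y1 = np.nanmean(x[post]), np.nanmean(y[post])
        dx, dy = x1 - x0, y1 - y0
        if not (np.isfinite(dx) and np.isfinite(dy)):
            dx = dy = 0.0
        events.append(
            SaccadeEvent(
                onset=float(t[s]),
                offset=float(t[min(e, t.size - 1)]),
                amplitude=float(np.hypot(dx, dy)),
                direction=float(np.arctan2(dy, dx)),
                peak_velocity=float(np.nanmax(v[s:e])),
            )
        )
    return events


def first_saccade_latency(events, stimulus_onset: float, window=(0.150, 0.300)):
    """Earliest saccade onset within ``[window)`` relative to the stimulus, or
    None if absent.  ``events`` may be SaccadeEvent objects or raw onset times."""
    latencies = []
    for ev in events:
        onset = ev.onset if isinstance(ev, SaccadeEvent) else float(ev)
        lat = onset - stimulus_onset
        if window[0] <= lat < window[1]:
            latencies.append(lat)
    return min(latencies) if latencies else None
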