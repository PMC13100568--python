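"""Sliding-window Hanning-taper time-frequency decomposition and band summaries."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import hann

__all__ = ["TFRMap", "tfr_hanning", "db_baseline", "remove_aperiodic", "band_power",
           "fit_aperiodic"]


@dataclass
class TFRMap:
    """Power container: (trials|1) x channels x freq x time.

    Also used to hold gaze-density maps (horizontal position on the time
    axis, vertical position on the frequency axis), so the statistics module
    can consume either without caring which it got.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: list = field(default_factory=list)
    baseline_window: tuple | None = None
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.ndim != 4:
            raise ValueError("power must be (trials, channels, freq, time)")
        if self.power.shape[2] != self.freqs.size or self.power.shape[3] != self.times.size:
            raise ValueError("axis mismatch")

    def freq_index(self, f: float) -> int:
        return int(np.argmin(np.abs(self.freqs - f)))

    def mean_over_trials(self) -> "TFRMap":
        return replace(self, power=self.power.mean(axis=0, keepdims=True))


def tfr_hanning(
    epochs,
    window: float = 0.5,
    step: float = 0.05,
    freqs=None,
) -> TFRMap:
    """Power at each (frequency, time) from Hanning-tapered sliding segments.

    The frequency grid defaults to 2..40 Hz in 2 Hz steps, the natural
    resolution of a 0.5 s window.  Time points are centres of complete
    windows only, stepped every ``step`` seconds; window centres are snapped
    to the nearest sample.
    """
    data = epochs.data  # trials x channels x time
    sr = epochs.sample_rate
    nwin = int(round(window * sr))
    if nwin > data.shape[2]:
        raise ValueError("window longer than epoch")
    if freqs is None:
        freqs = np.arange(2.0, 40.0 + 1e-9, 2.0)
    freqs = np.asarray(freqs, dtype=float)

    taper = hann(nwin, sym=False)
    # complex exponential basis, phase referenced to the window centre
    tau = (np.arange(nwin) - (nwin - 1) / 2) / sr
    basis = taper[None, :] * np.exp(-2j * np.pi * freqs[:, None] * tau[None, :])
    scale = 2.0 / (sr * np.sum(taper**2))  # one-sided PSD-style normalisation

    t0, t1 = epochs.times[0], epochs.times[-1]
    half = window / 2
    # centres on the absolute k*step grid; snapping with floor(x + 0.5) keeps
    # c_idx exactly shift-equivariant for shifts that are whole steps
    k0 = int(np.ceil((t0 + half) / step - 1e-9))
    k1 = int(np.floor((t1 - half) / step + 1e-9))
    if k1 < k0:
        raise ValueError("no complete window fits the epoch")
    ks = np.arange(k0, k1 + 1)
    centers = ks * step
    c_idx = np.floor(ks * (step * sr) - t0 * sr + 0.5).astype(int)
    # clamp so every window is complete
    c_idx = np.clip(c_idx, nwin // 2, data.shape[2] - (nwin - nwin // 2))

    n_tr, n_ch = data.shape[0], data.shape[1]
    power = np.empty((n_tr, n_ch, freqs.size, centers.size))
    flat = data.reshape(n_tr * n_ch, -1)
    for j, c in enumerate(c_idx):
        seg = flat[:, c - nwin // 2 : c - nwin // 2 + nwin]
        coef = seg @ basis.T.conj()
        power[:, :, :, j] = (np.abs(coef) ** 2).reshape(n_tr, n_ch, freqs.size) * scale
    return TFRMap(power=power, freqs=freqs, times=centers, channels=list(epochs.channels))


def db_baseline(tfr: TFRMap, window=(-np.inf, -0.25), per_trial: bool = False) -> TFRMap:
    """10*log10(power / baseline mean).

    The baseline mean is taken over the window's valid time points and, by
    default, over trials (per channel and frequency).  A -inf lower edge means
    "from the earliest valid time point".  Zero-power baseline cells yield NaN
    rather than infinities.
    """
    lo = max(window[0], tfr.times[0])
    sel = (tfr.times >= lo - 1e-12) & (tfr.times <= window[1] + 1e-12)
    if not sel.any():
        raise ValueError("baseline window has no valid time point")
    base = tfr.power[:, :, :, sel].mean(axis=3, keepdims=True)
    if not per_trial:
        base = base.mean(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 10.0 * np.log10(tfr.power / base)
    db[~np.isfinite(db)] = np.nan
    return replace(tfr, power=db, baseline_window=(lo, window[1]), units="dB")


def fit_aperiodic(freqs, spectrum, notch=(8.0, 13.0)):
    """Least-squares fit of log10(power) ~ a - b*log10(f), excluding the notch
    band and non-positive bins.  Returns (a, b)."""
    freqs = np.asarray(freqs, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    ok = (freqs > 0) & (spectrum > 0)
    if notch is not None:
        ok &= ~((freqs >= notch[0]) & (freqs <= notch[1]))
    if ok.sum() < 5:
        raise ValueError("need >= 5 usable frequency bins for the aperiodic fit")
    x = np.log10(freqs[ok])
    y = np.log10(spectrum[ok])
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(-slope)


def remove_aperiodic(freqs, spectrum, notch=(8.0, 13.0)):
    """Periodic residual: log10(power) minus the fitted aperiodic line.

    Non-positive power bins come back as NaN.
    """
    freqs = np.asarray(freqs, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    a, b = fit_aperiodic(freqs, spectrum, notch=notch)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.log10(spectrum) - (a - b * np.log10(freqs))
    resid[~np.isfinite(resid)] = np.nan
    return resid


def band_power(tfr: TFRMap, band=(8.0, 12.0), channels=None) -> np.ndarray:
    """Mean power over the band's frequency bins and the stated channels.

    Returns (trials, time).
    """
    sel = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    if not sel.any():
        raise ValueError("empty frequency band")
    if channels is None:
        ch_idx = slice(None)
    else:
        ch_idx = [tfr.channels.index(c) for c in channels]
    sub = tfr.power[:, ch_idx, :, :][:, :, sel, :]
    return sub.mean(axis=(1, 2))
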