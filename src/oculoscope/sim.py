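"""Generative model of saccade-coupled EEG.

EEG traces are built by strict linear superposition of three ingredients:

* a stereotyped biphasic kernel (positive bump followed by a deeper
  negative trough) placed so that its trough precedes each saccade onset
  by a fixed lag,
* small fixation-control deflections recurring every ~100 ms during the
  pre-stimulus fixation interval, and
* 1/f background noise.

No oscillatory source is ever injected; any narrow-band structure in the
output arises from the timing statistics of the event trains alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "TruncatedNormal",
    "Kernel",
    "EventTrainSpec",
    "SimConfig",
    "SimulatedTrial",
    "make_kernel",
    "sample_events",
    "synthesize_trial",
    "simulate_experiment",
    "one_over_f_noise",
]


# --------------------------------------------------------------------------- #
# distributions
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated normal distribution over a positive interval (seconds)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"bounds must satisfy 0 < lo < hi, got [{self.lo}, {self.hi}]")
        if not np.isfinite(self.mean) or not np.isfinite(self.sd) or self.sd <= 0:
            raise ValueError("mean must be finite and sd positive")

    def draw(self, rng: np.random.Generator, size=None):
        # inverse-CDF sampling (cheap and exactly reproducible from rng state)
        from scipy.special import ndtr, ndtri

        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        u = rng.uniform(ndtr(a), ndtr(b), size=size)
        return self.mean + self.sd * ndtri(u)

    @property
    def expected(self) -> float:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(stats.truncnorm(a, b, loc=self.mean, scale=self.sd).mean())


# --------------------------------------------------------------------------- #
# kernel
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Kernel:
    """Biphasic waveform whose trough precedes a saccade by ``pre_saccade_lag``.

    ``waveform`` holds the amplitude series sampled at ``sample_rate``;
    ``trough_offset`` is the time (s) from the start of the waveform to its
    most negative sample.
    """

    sample_rate: float
    waveform: np.ndarray
    trough_offset: float
    pre_saccade_lag: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.waveform.size) / self.sample_rate

    @property
    def integral(self) -> float:
        """Time-integral of the waveform (a.u. * s); its sign sets the polarity
        of the sustained component that accumulates under event overlap."""
        return float(np.sum(self.waveform) / self.sample_rate)


def make_kernel(
    p1_amp: float = 1.0,
    n170_amp: float = -1.5,
    p1_sigma: float = 0.015,
    n170_sigma: float = 0.020,
    p1_to_trough: float = 0.060,
    pre_saccade_lag: float = 0.120,
    sample_rate: float = 250.0,
) -> Kernel:
    """Build a positive-then-negative Gaussian-bump kernel.

    The positive bump (P1-like) is centred ``p1_to_trough`` seconds before the
    negative bump (N170-like trough).  ``p1_amp`` may be zero (degenerate) but
    must not be negative; ``n170_amp`` must be strictly negative.
    """
    for name, v in [("p1_amp", p1_amp), ("n170_amp", n170_amp)]:
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if p1_amp < 0:
        raise ValueError("p1_amp must be >= 0")
    if n170_amp >= 0:
        raise ValueError("n170_amp must be < 0")
    if p1_sigma <= 0 or n170_sigma <= 0:
        raise ValueError("sigmas must be > 0")
    if p1_to_trough <= 0:
        raise ValueError("p1_to_trough must be > 0")
    if pre_saccade_lag <= 0:
        raise ValueError("pre_saccade_lag must be > 0")

    pad = 4.0
    p1_center = pad * p1_sigma
    trough_center = p1_center + p1_to_trough
    total = trough_center + pad * n170_sigma
    n = int(round(total * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    wave = p1_amp * np.exp(-0.5 * ((t - p1_center) / p1_sigma) ** 2)
    wave += n170_amp * np.exp(-0.5 * ((t - trough_center) / n170_sigma) ** 2)
    trough_offset = float(t[np.argmin(wave)])
    return Kernel(
        sample_rate=sample_rate,
        waveform=wave,
        trough_offset=trough_offset,
        pre_saccade_lag=pre_saccade_lag,
    )


def make_control_kernel(
    amp: float = 0.4,
    lobe_sigma: float = 0.012,
    lobe_separation: float = 0.050,
    sample_rate: float = 250.0,
) -> Kernel:
    """Small zero-integral biphasic deflection used for fixation-control events.

    A positive and an equal negative Gaussian lobe separated by
    ``lobe_separation``; its integral is exactly zero, so a train of such
    deflections with stationary (stimulus-unlocked) timing cancels in the
    time-locked average while still carrying spectral power near
    ``1 / (2 * lobe_separation)``.
    """
    pad = 4.0
    c1 = pad * lobe_sigma
    c2 = c1 + lobe_separation
    n = int(round((c2 + pad * lobe_sigma) * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    wave = amp * np.exp(-0.5 * ((t - c1) / lobe_sigma) ** 2)
    wave -= amp * np.exp(-0.5 * ((t - c2) / lobe_sigma) ** 2)
    trough_offset = float(t[np.argmin(wave)])
    return Kernel(sample_rate=sample_rate, waveform=wave, trough_offset=trough_offset,
                  pre_saccade_lag=1e-3)


# --------------------------------------------------------------------------- #
# event trains
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class EventTrainSpec:
    """Statistics of one event train.

    kind:
        ``first_saccade`` -- single onset, latency drawn from
        ``first_latency_dist`` after the stimulus.
        ``exploratory_saccade`` -- renewal train started at an anchor (the
        first saccade), inter-event intervals from ``iei_dist`` divided by
        ``rate_scale`` and, optionally, inflated by an exponential taper so
        the rate decays over viewing time.
        ``fixation_control`` -- stationary renewal train confined to the
        pre-stimulus fixation interval.
    """

    kind: str
    first_latency_dist: TruncatedNormal | None = None
    iei_dist: TruncatedNormal | None = None
    rate_scale: float = 1.0
    taper: float = 0.0  # 1/s exponential decay of exploratory rate
    until: str = "stimulus"  # fixation_control only: "stimulus" | "window_end"

    def __post_init__(self) -> None:
        if self.kind not in ("first_saccade", "exploratory_saccade", "fixation_control"):
            raise ValueError(f"unknown event-train kind {self.kind!r}")
        if self.rate_scale < 0:
            raise ValueError("rate_scale must be >= 0")
        if self.kind == "first_saccade" and self.first_latency_dist is None:
            raise ValueError("first_saccade train needs first_latency_dist")
        if self.kind != "first_saccade" and self.iei_dist is None:
            raise ValueError(f"{self.kind} train needs iei_dist")


def sample_events(
    spec: EventTrainSpec,
    trial_window: tuple[float, float],
    stimulus_onset: float,
    seed,
) -> list[float]:
    """Draw event onsets (seconds, same clock as ``trial_window``).

    ``seed`` may be an int or a ``numpy.random.Generator``.  For the
    ``exploratory_saccade`` kind, ``stimulus_onset`` is the anchor after which
    the renewal train starts (the first-saccade onset) while taper time is
    measured from that anchor.
    """
    t0, t1 = trial_window
    if t1 <= t0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if spec.kind == "first_saccade":
        onset = stimulus_onset + float(spec.first_latency_dist.draw(rng))
        return [onset] if t0 <= onset < t1 else []

    if spec.rate_scale == 0:
        return []

    onsets: list[float] = []
    if spec.kind == "fixation_control":
        # stationary start: first event uniform within one interval of the
        # window start, so event phase is unlocked from the trial clock
        end = t1 if spec.until == "window_end" else min(stimulus_onset, t1)
        t = t0 + rng.uniform(0.0, float(spec.iei_dist.draw(rng)))
        while t < end:
            if t >= t0:
                onsets.append(t)
            t += float(spec.iei_dist.draw(rng)) / spec.rate_scale
        return onsets

    # exploratory_saccade
    t = stimulus_onset
    while True:
        base = float(spec.iei_dist.draw(rng)) / spec.rate_scale
        if spec.taper > 0:
            base *= float(np.exp(spec.taper * max(t - stimulus_onset, 0.0)))
        t = t + base
        if t >= t1:
            break
        onsets.append(t)
        if len(onsets) > 10_000:  # safety against pathological configs
            raise RuntimeError("exploratory train runaway; check iei_dist/rate_scale")
    return onsets


# --------------------------------------------------------------------------- #
# trial synthesis
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SimConfig:
    kernel: Kernel
    control_kernel: Kernel
    trains: dict  # condition -> list[EventTrainSpec]
    noise_exponent: float = 1.0
    noise_sd: float = 2.0
    n_trials: int = 1000
    epoch_window: tuple[float, float] = (-1.0, 2.0)
    sample_rate: float = 250.0
    seed: int = 0
    control_sign_mode: str = "balanced"  # "balanced" (same sign) | "alternate"

    def __post_init__(self) -> None:
        if not (self.epoch_window[0] < 0 < self.epoch_window[1]):
            raise ValueError("epoch_window must contain 0 (a baseline is required)")
        if self.sample_rate <= 2 * 40:
            raise ValueError("sample_rate must exceed twice the 40 Hz analysis ceiling")
        if self.control_sign_mode not in ("balanced", "alternate"):
            raise ValueError("control_sign_mode must be 'balanced' or 'alternate'")

    @property
    def conditions(self) -> list[str]:
        return list(self.trains)


@dataclass
class SimulatedTrial:
    eeg: np.ndarray  # (n_samples,) a.u.
    times: np.ndarray  # s, stimulus at 0
    saccade_onsets: np.ndarray
    control_onsets: np.ndarray
    condition: str
    ground_truth: dict


def trial_rng(master_seed: int, condition_index: int, trial_index: int) -> np.random.Generator:
    """Per-trial sub-generator: seeded by the (master, condition, trial) counter
    triple, so trials are reproducible independently of generation order."""
    return np.random.default_rng([int(master_seed), int(condition_index), int(trial_index)])


def one_over_f_noise(
    n: int, exponent: float, sd: float, rng: np.random.Generator, sample_rate: float = 250.0
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, scaled to given sd."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shaping, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _add_kernel(trace: np.ndarray, kernel_wave: np.ndarray, start_idx: int) -> bool:
    """Add a kernel copy starting at sample ``start_idx``; truncate at the trial
    boundaries.  Returns True if any truncation occurred."""
    n = trace.size
    k = kernel_wave.size
    lo = max(start_idx, 0)
    hi = min(start_idx + k, n)
    if hi <= lo:
        return True
    trace[lo:hi] += kernel_wave[lo - start_idx : hi - start_idx]
    return lo != start_idx or hi != start_idx + k


def synthesize_trial(config: SimConfig, condition: str, trial_index: int) -> SimulatedTrial:
    """Generate one trial as a strict linear superposition of kernel copies,
    control deflections, and 1/f noise."""
    if condition not in config.trains:
        raise ValueError(f"unknown condition {condition!r}")
    cond_index = config.conditions.index(condition)
    rng = trial_rng(config.seed, cond_index, trial_index)
    t0, t1 = config.epoch_window
    sr = config.sample_rate
    n = int(round((t1 - t0) * sr))
    times = t0 + np.arange(n) / sr

    saccades: list[float] = []
    controls: list[float] = []
    first_latency = np.nan
    for spec in config.trains[condition]:
        if spec.kind == "first_saccade":
            ev = sample_events(spec, (t0, t1), 0.0, rng)
            if ev:
                first_latency = ev[0]
                saccades.extend(ev)
        elif spec.kind == "exploratory_saccade":
            anchor = first_latency if np.isfinite(first_latency) else 0.0
            saccades.extend(sample_events(spec, (t0, t1), anchor, rng))
        else:
            # burn-in: sample from before the window so the control process is
            # stationary in view; pre-window events contribute clipped tails
            # but are not reported as onsets
            controls.extend(sample_events(spec, (t0 - 0.5, t1), 0.0, rng))
    saccades = sorted(saccades)
    controls = sorted(controls)

    trace = np.zeros(n)
    truncated = False
    for s in saccades:
        # kernel trough lands pre_saccade_lag before the saccade onset
        start_t = s - config.kernel.pre_saccade_lag - config.kernel.trough_offset
        idx = int(round((start_t - t0) * sr))
        truncated |= _add_kernel(trace, config.kernel.waveform, idx)
    # alternate mode: strict pairwise sign balance within the trial, but with a
    # random starting sign so the time-locked expectation is exactly zero
    # (event parity correlates with time from the window start otherwise)
    start_sign = 1.0 if config.control_sign_mode != "alternate" else rng.choice([-1.0, 1.0])
    for i, c in enumerate(controls):
        sign = start_sign * (-1.0) ** i if config.control_sign_mode == "alternate" else 1.0
        idx = int(round((c - t0) * sr))
        truncated |= _add_kernel(trace, sign * config.control_kernel.waveform, idx)
    all_controls = list(controls)
    controls = [c for c in controls if c >= t0]  # burn-in events are not reported
    trace += one_over_f_noise(n, config.noise_exponent, config.noise_sd, rng, sr)

    return SimulatedTrial(
        eeg=trace,
        times=times,
        saccade_onsets=np.asarray(saccades),
        control_onsets=np.asarray(controls),
        condition=condition,
        ground_truth={
            "pre_saccade_lag": config.kernel.pre_saccade_lag,
            "first_saccade_latency": first_latency,
            "n_saccades": len(saccades),
            "n_controls": len(controls),
            "saccade_onsets": np.asarray(saccades),
            "control_onsets": np.asarray(controls),
            "control_onsets_with_burnin": np.asarray(all_controls),
            "kernel_truncated": truncated,
        },
    )


def simulate_experiment(config: SimConfig):
    """Simulate ``config.n_trials`` trials per condition.

    Returns a stimulus-aligned :class:`~oculoscope.erp.Epochs` plus an event
    table on a concatenated session clock (trial k occupies
    ``[k*D, (k+1)*D)`` with the stimulus at ``k*D - epoch_window[0]``).
    """
    from .erp import Epochs  # local import to avoid a cycle
    from .io import EventTable

    t0, t1 = config.epoch_window
    dur = t1 - t0
    rows = []
    data = []
    meta_rows = []
    trial_counter = 0
    for ci, cond in enumerate(config.conditions):
        for ti in range(config.n_trials):
            trial = synthesize_trial(config, cond, ti)
            offset = trial_counter * dur
            stim = offset - t0
            data.append(trial.eeg)
            meta_rows.append(
                {
                    "condition": cond,
                    "trial_id": trial_counter,
                    "first_saccade_latency": trial.ground_truth["first_saccade_latency"],
                }
            )
            rows.append((stim, 0.0, "stimulus_on", cond, trial_counter))
            for s in trial.saccade_onsets:
                rows.append((stim + s, 0.0, "saccade", cond, trial_counter))
            for c in trial.control_onsets:
                rows.append((stim + c, 0.0, "fixation_control", cond, trial_counter))
            trial_counter += 1

    import pandas as pd

    meta = pd.DataFrame(meta_rows)
    events = EventTable(
        pd.DataFrame(rows, columns=["onset", "duration", "type", "condition", "trial_id"])
        .sort_values("onset", kind="stable")
        .reset_index(drop=True)
    )
    arr = np.asarray(data)[:, None, :]  # trials x 1 channel x time
    n = arr.shape[2]
    times = t0 + np.arange(n) / config.sample_rate
    epochs = Epochs(
        data=arr,
        times=times,
        sample_rate=config.sample_rate,
        channels=["POz"],
        alignment="stimulus",
        meta=meta,
    )
    return epochs, events


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
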