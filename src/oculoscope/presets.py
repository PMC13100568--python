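"""Bundled simulation presets and config-file (de)serialisation.

Preset names follow the demo-experiment registry (``figS4``: ERP + sustained
slow component from condition-dependent exploration rates; ``figS5``: the
same plus fixation-control trains whose ~100 ms recurrence yields alpha-band
structure; ``eyes_closed``: still-vs-move conditions with no stimulus-driven
kernel difference).
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from .sim import (
    EventTrainSpec,
    Kernel,
    SimConfig,
    TruncatedNormal,
    make_control_kernel,
    make_kernel,
)

__all__ = ["fig_s4", "fig_s5", "eyes_closed", "get_preset", "PRESETS",
           "config_from_dict", "config_to_dict", "load_config"]


def _saccade_kernel(sample_rate: float = 250.0, p_amp: float = 3.2,
                    n_amp: float = -6.0, p_sigma: float = 0.022,
                    n_sigma: float = 0.015, separation: float = 0.065,
                    pre_saccade_lag: float = 0.120) -> Kernel:
    """Symmetric triphasic kernel (P1 - trough - P2 rebound).

    Symmetry about the trough keeps the trough of the latency-smeared average
    at mean(latency) - lag (an asymmetric kernel biases the smeared argmin);
    the net positive time-integral makes overlapping copies accumulate into a
    positive sustained component.
    """
    pad = 4.0
    c = pad * p_sigma + separation
    total = c + separation + pad * p_sigma
    n = int(round(total * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    wave = p_amp * np.exp(-0.5 * ((t - (c - separation)) / p_sigma) ** 2)
    wave += n_amp * np.exp(-0.5 * ((t - c) / n_sigma) ** 2)
    wave += p_amp * np.exp(-0.5 * ((t - (c + separation)) / p_sigma) ** 2)
    trough_offset = float(t[np.argmin(wave)])
    return Kernel(sample_rate=sample_rate, waveform=wave, trough_offset=trough_offset,
                  pre_saccade_lag=pre_saccade_lag)


FIRST_LATENCY = TruncatedNormal(mean=0.290, sd=0.040, lo=0.150, hi=0.450)
EXPLORATORY_IEI = TruncatedNormal(mean=0.300, sd=0.080, lo=0.120, hi=0.800)
CONTROL_IEI = TruncatedNormal(mean=0.105, sd=0.015, lo=0.060, hi=0.200)


def _exploration_trains(rate_scale: float, with_control: bool) -> list:
    trains = [
        EventTrainSpec(kind="first_saccade", first_latency_dist=FIRST_LATENCY),
        EventTrainSpec(
            kind="exploratory_saccade",
            iei_dist=EXPLORATORY_IEI,
            rate_scale=rate_scale,
            taper=0.5,
        ),
    ]
    if with_control:
        trains.append(EventTrainSpec(kind="fixation_control", iei_dist=CONTROL_IEI))
    return trains


def fig_s4(n_trials: int = 1000, seed: int = 0, sample_rate: float = 250.0) -> SimConfig:
    """High- vs low-exploration conditions; saccade kernels + 1/f noise only."""
    return SimConfig(
        kernel=_saccade_kernel(sample_rate),
        control_kernel=make_control_kernel(sample_rate=sample_rate),
        trains={
            "high": _exploration_trains(1.0, with_control=False),
            "low": _exploration_trains(0.6, with_control=False),
        },
        noise_exponent=1.0,
        noise_sd=2.0,
        n_trials=n_trials,
        epoch_window=(-1.0, 2.0),
        sample_rate=sample_rate,
        seed=seed,
    )


def fig_s5(n_trials: int = 1000, seed: int = 0, sample_rate: float = 250.0,
           kernel_scale: float = 0.2, control_amp: float = 0.8) -> SimConfig:
    """As ``fig_s4`` plus stationary fixation-control trains in the baseline.

    Control deflections are zero-integral biphasic waveforms recurring every
    ~105 ms; their stimulus-unlocked timing cancels them in the ERP while the
    recurrence statistics concentrate spectral power near 1/IEI (8-10 Hz).
    The saccade kernel is scaled down relative to the ERP preset so the
    alpha-band comparison is dominated by the presence/absence of fixation
    control rather than by broadband saccadic transients.
    """
    import dataclasses

    k = _saccade_kernel(sample_rate)
    k = dataclasses.replace(k, waveform=k.waveform * kernel_scale)
    return SimConfig(
        kernel=k,
        control_kernel=make_control_kernel(amp=control_amp, lobe_sigma=0.012,
                                           lobe_separation=0.050, sample_rate=sample_rate),
        trains={
            "high": _exploration_trains(1.0, with_control=True),
            "low": _exploration_trains(0.6, with_control=True),
        },
        noise_exponent=1.0,
        noise_sd=2.0,
        n_trials=n_trials,
        epoch_window=(-2.0, 2.0),
        sample_rate=sample_rate,
        seed=seed,
        control_sign_mode="balanced",
    )


def eyes_closed(n_trials: int = 200, seed: int = 0, sample_rate: float = 250.0,
                kernel_scale: float = 0.2, control_amp: float = 0.8) -> SimConfig:
    """Still vs move: the still condition keeps fixation-control events running
    through the whole trial; the move condition releases fixation at 'task'
    onset and launches an exploratory saccade train instead."""
    import dataclasses

    k = _saccade_kernel(sample_rate)
    k = dataclasses.replace(k, waveform=k.waveform * kernel_scale)
    still_control = EventTrainSpec(kind="fixation_control", iei_dist=CONTROL_IEI,
                                   until="window_end")
    return SimConfig(
        kernel=k,
        control_kernel=make_control_kernel(amp=control_amp, sample_rate=sample_rate),
        trains={
            "still": [still_control],
            "move": _exploration_trains(1.0, with_control=True),
        },
        noise_exponent=1.0,
        noise_sd=2.0,
        n_trials=n_trials,
        epoch_window=(-2.0, 2.0),
        sample_rate=sample_rate,
        seed=seed,
    )


PRESETS = {"figS4": fig_s4, "figS5": fig_s5, "eyes_closed": eyes_closed}


def get_preset(name: str, **kwargs) -> SimConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](**kwargs)


# --------------------------------------------------------------------------- #
# config files
# --------------------------------------------------------------------------- #


def _dist_to_dict(d: TruncatedNormal | None):
    return None if d is None else {"mean": d.mean, "sd": d.sd, "lo": d.lo, "hi": d.hi}


def config_to_dict(cfg: SimConfig) -> dict:
    return {
        "schema_version": 1,
        "sample_rate": cfg.sample_rate,
        "epoch_window": list(cfg.epoch_window),
        "n_trials": cfg.n_trials,
        "seed": cfg.seed,
        "noise": {"exponent": cfg.noise_exponent, "sd": cfg.noise_sd},
        "control_sign_mode": cfg.control_sign_mode,
        "kernel": {
            "waveform": [float(v) for v in cfg.kernel.waveform],
            "trough_offset": cfg.kernel.trough_offset,
            "pre_saccade_lag": cfg.kernel.pre_saccade_lag,
        },
        "control_kernel": {
            "waveform": [float(v) for v in cfg.control_kernel.waveform],
            "trough_offset": cfg.control_kernel.trough_offset,
            "pre_saccade_lag": cfg.control_kernel.pre_saccade_lag,
        },
        "trains": {
            cond: [
                {
                    "kind": s.kind,
                    "first_latency_dist": _dist_to_dict(s.first_latency_dist),
                    "iei_dist": _dist_to_dict(s.iei_dist),
                    "rate_scale": s.rate_scale,
                    "taper": s.taper,
                }
                for s in specs
            ]
            for cond, specs in cfg.trains.items()
        },
    }


def _dist_from_dict(d):
    return None if d is None else TruncatedNormal(**d)


def config_from_dict(d: dict) -> SimConfig:
    if "preset" in d:
        base = dict(d)
        name = base.pop("preset")
        base.pop("schema_version", None)
        return get_preset(name, **base)
    sr = float(d["sample_rate"])
    kern = d["kernel"]
    ckern = d["control_kernel"]
    kernel = Kernel(
        sample_rate=sr,
        waveform=np.asarray(kern["waveform"], dtype=float),
        trough_offset=float(kern["trough_offset"]),
        pre_saccade_lag=float(kern["pre_saccade_lag"]),
    )
    control = Kernel(
        sample_rate=sr,
        waveform=np.asarray(ckern["waveform"], dtype=float),
        trough_offset=float(ckern["trough_offset"]),
        pre_saccade_lag=float(ckern["pre_saccade_lag"]),
    )
    trains = {
        cond: [
            EventTrainSpec(
                kind=s["kind"],
                first_latency_dist=_dist_from_dict(s.get("first_latency_dist")),
                iei_dist=_dist_from_dict(s.get("iei_dist")),
                rate_scale=float(s.get("rate_scale", 1.0)),
                taper=float(s.get("taper", 0.0)),
            )
            for s in specs
        ]
        for cond, specs in d["trains"].items()
    }
    return SimConfig(
        kernel=kernel,
        control_kernel=control,
        trains=trains,
        noise_exponent=float(d["noise"]["exponent"]),
        noise_sd=float(d["noise"]["sd"]),
        n_trials=int(d["n_trials"]),
        epoch_window=tuple(d["epoch_window"]),
        sample_rate=sr,
        seed=int(d.get("seed", 0)),
        control_sign_mode=d.get("control_sign_mode", "balanced"),
    )


def load_config(path) -> SimConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))
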