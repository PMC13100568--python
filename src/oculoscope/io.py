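"""Synthetic sessions (EEG + gaze + events) and the on-disk TSV formats.

The TSV dialect is the contract: UTF-8, tab-separated, one header line for
gaze/events, a two-line header for EEG (line 1: sample rate, line 2: channel
labels).  Missing gaze is written as empty fields with ``lost=1``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sim import SimConfig, one_over_f_noise, synthesize_trial, trial_rng

__all__ = [
    "Screen",
    "GazeRecording",
    "EEGRecording",
    "EventTable",
    "GazeConfig",
    "generate_session",
    "write_session",
    "read_session",
    "SessionPaths",
    "FormatError",
]

EVENT_TYPES = {"stimulus_on", "stimulus_off", "saccade", "fixation_control", "blink"}


class FormatError(ValueError):
    pass


@dataclass(frozen=True)
class Screen:
    width_px: int = 1920
    height_px: int = 1080
    width_cm: float = 60.0
    distance_cm: float = 70.0

    def px_to_dva(self, px: float) -> float:
        cm = px * self.width_cm / self.width_px
        return float(np.degrees(2 * np.arctan2(cm / 2, self.distance_cm)))


@dataclass
class GazeRecording:
    time: np.ndarray  # s, uniform
    x: np.ndarray  # px, NaN when lost
    y: np.ndarray
    pupil: np.ndarray  # mm, may be NaN
    loss_mask: np.ndarray
    screen: Screen = field(default_factory=Screen)
    sample_rate: float = 250.0

    def __post_init__(self) -> None:
        dt = np.diff(self.time)
        if dt.size and (dt.min() <= 0 or np.abs(dt - 1.0 / self.sample_rate).max() > 1e-9):
            raise ValueError("time base must be strictly increasing and uniform")


@dataclass
class EEGRecording:
    sample_rate: float
    labels: list
    data: np.ndarray  # channels x samples, a.u. standing for uV

    def __post_init__(self) -> None:
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count must equal channel count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")


class EventTable:
    """Thin wrapper over a DataFrame with onset/duration/type/condition/trial_id."""

    COLUMNS = ["onset", "duration", "type", "condition", "trial_id"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        df = df[self.COLUMNS].reset_index(drop=True)
        if len(df):
            onsets = df["onset"].to_numpy(dtype=float)
            if (onsets < 0).any():
                raise ValueError("event onsets must be non-negative")
            if not (np.diff(onsets) >= -1e-12).all():
                raise ValueError("event onsets must be sorted")
            bad = set(df["type"]) - EVENT_TYPES
            if bad:
                raise ValueError(f"unknown event types {sorted(bad)}")
            with_sacc = set(df.loc[df["type"] == "saccade", "trial_id"])
            with_stim = set(df.loc[df["type"] == "stimulus_on", "trial_id"])
            if not with_sacc <= with_stim:
                raise ValueError("every trial with a saccade needs a stimulus_on")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self.df.equals(other.df)

    def of_type(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["type"] == kind]

    def stimulus_onsets(self) -> np.ndarray:
        return self.of_type("stimulus_on")["onset"].to_numpy(dtype=float)


# --------------------------------------------------------------------------- #
# session generation
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class GazeConfig:
    screen: Screen = field(default_factory=Screen)
    fixation_jitter_sd: float = 8.0  # px, stationary sd of fixational wander
    jitter_pullback: float = 20.0  # 1/s mean-reversion toward the target
    saccade_step_px: float = 200.0  # typical saccadic displacement
    saccade_rise: float = 0.025  # s, smooth-step duration
    blink_rate: float = 0.1  # 1/s
    blink_duration: float = 0.2  # s
    baseline_range: tuple = (2.5, 3.5)  # s, uniform jittered fixation duration
    pupil_mm: float = 3.5


#: session presets mirroring the bundled task timings
SESSION_PRESETS = {
    "face": {"baseline_range": (2.5, 3.5), "viewing": 5.0},
    "iaps": {"baseline_range": (1.0, 2.0), "viewing": 1.0},
    "eyes-closed": {"baseline_range": (3.5, 4.5), "viewing": 6.0},
}

POSTERIOR_GAINS = {"O1": 1.0, "O2": 1.0, "POz": 0.8}
DEFAULT_LABELS = ["O1", "O2", "POz", "Pz", "P3", "P4", "Cz", "Fz"]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3 - 2 * u)


def generate_session(
    sim_config: SimConfig,
    gaze_config: GazeConfig | None = None,
    seed: int = 0,
    viewing: float | None = None,
    labels=None,
):
    """Concatenate simulated trials into a continuous session.

    Per trial: a jittered baseline fixation interval, then the post-stimulus
    viewing interval.  The simulator's single-channel trace lands on the
    posterior channels (gain per channel); the other channels carry
    independent 1/f noise.  The gaze trace is a mean-reverting fixational
    wander plus a ~25 ms smooth step toward a random target at each saccade,
    with blink gaps marked in ``loss_mask``.
    """
    gc = gaze_config or GazeConfig()
    rng = np.random.default_rng([int(seed), 0xD15EA5E])
    sr = sim_config.sample_rate
    view = viewing if viewing is not None else sim_config.epoch_window[1]
    lab = list(labels) if labels is not None else list(DEFAULT_LABELS)

    import dataclasses

    n_total = sim_config.n_trials * len(sim_config.conditions)
    baselines = rng.uniform(*gc.baseline_range, size=n_total)

    eeg_parts, rows = [], []
    sacc_sess, stim_sess = [], []
    cursor = 0.0
    trial_counter = 0
    for ci, cond in enumerate(sim_config.conditions):
        for ti in range(sim_config.n_trials):
            b = baselines[trial_counter]
            cfg = dataclasses.replace(sim_config, epoch_window=(-float(b), float(view)))
            trial = synthesize_trial(cfg, cond, ti)
            stim = cursor + b
            eeg_parts.append(trial.eeg)
            rows.append((stim, view, "stimulus_on", cond, trial_counter))
            rows.append((stim + view, 0.0, "stimulus_off", cond, trial_counter))
            for s in trial.saccade_onsets:
                rows.append((stim + s, 0.0, "saccade", cond, trial_counter))
                sacc_sess.append(stim + s)
            for c in trial.control_onsets:
                rows.append((stim + c, 0.0, "fixation_control", cond, trial_counter))
            stim_sess.append(stim)
            cursor += b + view
            trial_counter += 1

    source = np.concatenate(eeg_parts)
    n = source.size
    time = np.arange(n) / sr

    data = np.empty((len(lab), n))
    for i, name in enumerate(lab):
        gain = POSTERIOR_GAINS.get(name, 0.0)
        ch_rng = np.random.default_rng([int(seed), 1, i])
        noise = one_over_f_noise(n, sim_config.noise_exponent, sim_config.noise_sd, ch_rng, sr)
        data[i] = gain * source + (noise if gain == 0.0 else 0.25 * noise)
    eeg = EEGRecording(sample_rate=sr, labels=lab, data=data)

    # ---- gaze -------------------------------------------------------------
    cx, cy = gc.screen.width_px / 2, gc.screen.height_px / 2
    base_x = np.full(n, cx)
    base_y = np.full(n, cy)
    target = np.array([cx, cy])
    change_points = sorted((s, "saccade") for s in sacc_sess)
    # displacement profile per saccade
    for s, _ in change_points:
        ang = rng.uniform(-np.pi, np.pi)
        step = gc.saccade_step_px * rng.uniform(0.6, 1.4)
        new = target + step * np.array([np.cos(ang), np.sin(ang)])
        new[0] = np.clip(new[0], 0.1 * gc.screen.width_px, 0.9 * gc.screen.width_px)
        new[1] = np.clip(new[1], 0.1 * gc.screen.height_px, 0.9 * gc.screen.height_px)
        i0 = int(round(s * sr))
        if i0 >= n:
            continue
        ramp = _smoothstep((time[i0:] - s) / gc.saccade_rise)
        base_x[i0:] += (new[0] - target[0]) * ramp
        base_y[i0:] += (new[1] - target[1]) * ramp
        target = new
    # snap back to fixation at each stimulus offset / trial start
    for k, stim in enumerate(stim_sess):
        i0 = int(round((stim + view) * sr))
        if i0 < n:
            base_x[i0:] += cx - base_x[i0]
            base_y[i0:] += cy - base_y[i0]

    # mean-reverting fixational wander around the base trajectory
    dt = 1.0 / sr
    theta = gc.jitter_pullback
    sigma = gc.fixation_jitter_sd * np.sqrt(2 * theta)
    wander = np.zeros((2, n))
    eps = rng.standard_normal((2, n))
    for i in range(1, n):
        wander[:, i] = wander[:, i - 1] * (1 - theta * dt) + sigma * np.sqrt(dt) * eps[:, i]
    x = base_x + wander[0]
    y = base_y + wander[1]
    np.clip(x, 0, gc.screen.width_px, out=x)
    np.clip(y, 0, gc.screen.height_px, out=y)

    loss = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(gc.blink_rate * n / sr)
    for onset in np.sort(rng.uniform(0, n / sr - gc.blink_duration, size=n_blinks)):
        i0 = int(round(onset * sr))
        i1 = min(int(round((onset + gc.blink_duration) * sr)), n)
        loss[i0:i1] = True
        rows.append((onset, gc.blink_duration, "blink", "na", -1))
    x[loss] = np.nan
    y[loss] = np.nan
    pupil = np.full(n, gc.pupil_mm) + 0.05 * wander[0] / max(gc.fixation_jitter_sd, 1e-9)
    pupil[loss] = np.nan

    gaze = GazeRecording(
        time=time, x=x, y=y, pupil=pupil, loss_mask=loss, screen=gc.screen, sample_rate=sr
    )
    events = EventTable(
        pd.DataFrame(rows, columns=EventTable.COLUMNS)
        .sort_values("onset", kind="stable")
        .reset_index(drop=True)
    )
    return eeg, gaze, events


# --------------------------------------------------------------------------- #
# on-disk formats
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SessionPaths:
    eeg: str
    gaze: str
    events: str

    @classmethod
    def in_dir(cls, d) -> "SessionPaths":
        d = str(d)
        return cls(
            eeg=os.path.join(d, "eeg.tsv"),
            gaze=os.path.join(d, "gaze.tsv"),
            events=os.path.join(d, "events.tsv"),
        )


def write_session(paths: SessionPaths, eeg: EEGRecording, gaze: GazeRecording,
                  events: EventTable) -> None:
    os.makedirs(os.path.dirname(paths.eeg) or ".", exist_ok=True)
    with open(paths.eeg, "w", encoding="utf-8") as fh:
        fh.write(f"sample_rate_hz\t{eeg.sample_rate!r}\n")
        fh.write("\t".join(eeg.labels) + "\n")
        np.savetxt(fh, eeg.data.T, fmt="%.8g", delimiter="\t")

    with open(paths.gaze, "w", encoding="utf-8") as fh:
        fh.write("time_s\tx_px\ty_px\tpupil_mm\tlost\n")
        for i in range(gaze.time.size):
            if gaze.loss_mask[i]:
                fh.write(f"{gaze.time[i]:.8g}\t\t\t\t1\n")
            else:
                fh.write(
                    f"{gaze.time[i]:.8g}\t{gaze.x[i]:.8g}\t{gaze.y[i]:.8g}"
                    f"\t{gaze.pupil[i]:.8g}\t0\n"
                )

    with open(paths.events, "w", encoding="utf-8") as fh:
        fh.write("onset_s\tduration_s\ttype\tcondition\ttrial_id\n")
        for row in events.df.itertuples(index=False):
            fh.write(f"{row.onset:.8g}\t{row.duration:.8g}\t{row.type}\t{row.condition}"
                     f"\t{row.trial_id}\n")


def read_session(paths: SessionPaths, screen: Screen | None = None):
    # ---- EEG --------------------------------------------------------------
    with open(paths.eeg, encoding="utf-8") as fh:
        head = fh.readline().rstrip("\n").split("\t")
        if len(head) != 2 or head[0] != "sample_rate_hz":
            raise FormatError(f"{paths.eeg}:1: expected 'sample_rate_hz\\t<rate>'")
        sr = float(head[1])
        labels = fh.readline().rstrip("\n").split("\t")
        try:
            mat = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{paths.eeg}: malformed data matrix: {exc}") from exc
    if mat.size and mat.shape[1] != len(labels):
        raise FormatError(f"{paths.eeg}:2: {len(labels)} labels but {mat.shape[1]} columns")
    eeg = EEGRecording(sample_rate=sr, labels=labels, data=mat.T)

    # ---- gaze -------------------------------------------------------------
    gdf = pd.read_csv(paths.gaze, sep="\t", dtype=str, keep_default_na=False)
    expected = ["time_s", "x_px", "y_px", "pupil_mm", "lost"]
    if list(gdf.columns) != expected:
        raise FormatError(f"{paths.gaze}:1: header must be {expected}")

    def _col(name):
        return pd.to_numeric(gdf[name].replace("", np.nan)).to_numpy(dtype=float)

    time = _col("time_s")
    x = _col("x_px")
    y = _col("y_px")
    pupil = _col("pupil_mm")
    lost = gdf["lost"].astype(int).to_numpy(dtype=bool)
    lost |= ~np.isfinite(x) | ~np.isfinite(y)
    dt = np.diff(time)
    if dt.size:
        sr_gaze = 1.0 / np.median(dt)
        if (dt <= 0).any() or np.abs(dt - 1.0 / sr_gaze).max() > 1e-6:
            raise FormatError(f"{paths.gaze}: non-uniform time base")
    else:
        sr_gaze = sr
    gaze = GazeRecording(
        time=time, x=x, y=y, pupil=pupil, loss_mask=lost,
        screen=screen or Screen(), sample_rate=float(round(sr_gaze, 6)),
    )

    # ---- events -----------------------------------------------------------
    edf = pd.read_csv(paths.events, sep="\t", dtype={"type": str, "condition": str},
                      keep_default_na=False)
    edf.columns = [c.strip() for c in edf.columns]
    rename = {"onset_s": "onset", "duration_s": "duration"}
    edf = edf.rename(columns=rename)
    if len(edf):
        bad = set(edf["type"]) - EVENT_TYPES
        if bad:
            line = edf.index[edf["type"].isin(bad)][0] + 2
            raise FormatError(f"{paths.events}:{line}: unknown event type {sorted(bad)[0]!r}")
        edf["onset"] = edf["onset"].astype(float)
        edf["duration"] = edf["duration"].astype(float)
        edf["trial_id"] = edf["trial_id"].astype(int)
    else:
        edf = pd.DataFrame(columns=EventTable.COLUMNS)
    events = EventTable(edf)
    return eeg, gaze, events
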