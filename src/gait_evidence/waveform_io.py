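"""Reading, validation, normalization and ensemble averaging of gait waveforms.

Conventions
-----------
* Every stored curve has exactly 101 samples (0..100 % of stance or cycle).
* Ground reaction forces are expressed as a fraction of body weight
  (``force / (mass * g)``); joint moments as a percentage of bodyweight times
  height (``100 * moment / (mass * g * height)``).
* Ensemble curves are pointwise means of time-normalized trials; at least
  ``min_trials`` (default 3) trials are required per subject and channel.

CSV dialects
------------
Trial (long) CSV: ``subject_id, visit, channel, trial, t_index, value`` with
``t_index`` 0..100.  Ensemble (wide) CSV: ``subject_id, visit, channel,
v000..v100``.  UTF-8, "." decimal, header row required.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNEL_PHASE, CHANNEL_UNITS, N_SAMPLES

#: standard gravity, m/s^2
G = 9.81


class InsufficientDataError(ValueError):
    """Fewer usable trials than the required minimum."""


@dataclass
class Trial:
    """A single walking trial for one subject and one waveform channel."""

    subject_id: str
    channel: str
    samples: np.ndarray
    phase: str = "cycle"
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a trial needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trial contains missing or non-finite values")


def time_normalize(trial: Trial | Sequence[float], n_points: int = N_SAMPLES) -> np.ndarray:
    """Linearly resample a trial onto ``n_points`` equally spaced points.

    The resampling grid spans the first to the last sample, so endpoints are
    preserved exactly; a curve already on the target grid is returned
    unchanged (up to float identity).
    """
    samples = trial.samples if isinstance(trial, Trial) else np.asarray(trial, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    x_old = np.linspace(0.0, 1.0, samples.size)
    x_new = np.linspace(0.0, 1.0, n_points)
    return np.interp(x_new, x_old, samples)


def normalize_grf(force_n: Sequence[float], mass_kg: float, *, divisor: str = "weight") -> np.ndarray:
    """Scale a ground-reaction-force curve (N) to a fraction of body weight.

    ``divisor="weight"`` divides by ``mass_kg * g`` (the default);
    ``divisor="mass"`` divides by ``mass_kg`` alone, for studies that report
    N/kg.
    """
    if mass_kg <= 0:
        raise ValueError("mass_kg must be positive")
    force = np.asarray(force_n, dtype=float)
    if divisor == "weight":
        return force / (mass_kg * G)
    if divisor == "mass":
        return force / mass_kg
    raise ValueError(f"unknown grf divisor: {divisor!r}")


def normalize_moment(moment_nm: Sequence[float], mass_kg: float, height_m: float) -> np.ndarray:
    """Scale a joint-moment curve (Nm) to percent bodyweight times height."""
    if mass_kg <= 0:
        raise ValueError("mass_kg must be positive")
    if height_m <= 0:
        raise ValueError("height_m must be positive")
    return 100.0 * np.asarray(moment_nm, dtype=float) / (mass_kg * G * height_m)


def denormalize_moment(moment_pct: Sequence[float], mass_kg: float, height_m: float) -> np.ndarray:
    """Inverse of :func:`normalize_moment` (back to Nm)."""
    return np.asarray(moment_pct, dtype=float) * mass_kg * G * height_m / 100.0


def ensemble_average(trials: Sequence[Trial], min_trials: int = 3) -> np.ndarray:
    """Pointwise mean of a subject's time-normalized trials for one channel.

    Raises :class:`InsufficientDataError` when fewer than ``min_trials``
    trials remain (after any upstream exclusions), and ``ValueError`` when
    trials mix subjects, channels or phases.
    """
    if len(trials) < min_trials:
        raise InsufficientDataError(
            f"need at least {min_trials} trials, got {len(trials)}"
        )
    keys = {(t.subject_id, t.channel, t.phase) for t in trials}
    if len(keys) != 1:
        raise ValueError(f"trials mix subjects/channels/phases: {sorted(keys)}")
    stack = np.vstack([time_normalize(t) for t in trials])
    return stack.mean(axis=0)


@dataclass
class WaveformSet:
    """Ensemble gait curves for a cohort: subjects x channels x 101 samples."""

    subjects: list[str]
    channels: list[str]
    data: np.ndarray  # (n_subjects, n_channels, 101)
    mass_kg: np.ndarray | None = None
    height_m: np.ndarray | None = None
    visit: str = "pre"
    phase: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n_s, n_c = len(self.subjects), len(self.channels)
        if self.data.shape != (n_s, n_c, N_SAMPLES):
            raise ValueError(
                f"data shape {self.data.shape} != ({n_s}, {n_c}, {N_SAMPLES}); "
                "curves must have exactly 101 samples"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("waveform data contains non-finite values")
        if not self.phase:
            self.phase = {c: CHANNEL_PHASE.get(c, "cycle") for c in self.channels}
        if not self.units:
            self.units = {c: CHANNEL_UNITS.get(c, "") for c in self.channels}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def curve(self, subject: str, channel: str) -> np.ndarray:
        return self.data[self.subjects.index(subject), self.channels.index(channel)]

    def subset(self, subjects: Iterable[str]) -> "WaveformSet":
        subjects = list(subjects)
        idx = [self.subjects.index(s) for s in subjects]
        return WaveformSet(
            subjects=subjects,
            channels=list(self.channels),
            data=self.data[idx],
            mass_kg=None if self.mass_kg is None else self.mass_kg[idx],
            height_m=None if self.height_m is None else self.height_m[idx],
            visit=self.visit,
            phase=dict(self.phase),
            units=dict(self.units),
        )

    # --- wide ensemble CSV -------------------------------------------------

    def to_wide_frame(self) -> pd.DataFrame:
        cols = [f"v{i:03d}" for i in range(N_SAMPLES)]
        rows = []
        for si, subj in enumerate(self.subjects):
            for ci, chan in enumerate(self.channels):
                rows.append([subj, self.visit, chan] + list(self.data[si, ci]))
        return pd.DataFrame(rows, columns=["subject_id", "visit", "channel"] + cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_wide_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        mass_kg: dict[str, float] | None = None,
        height_m: dict[str, float] | None = None,
    ) -> "WaveformSet":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"subject_id", "visit", "channel"}
        if not required.issubset(df.columns):
            raise ValueError(f"ensemble CSV missing columns {required - set(df.columns)}")
        value_cols = [c for c in df.columns if re.fullmatch(r"v\d{3}", c)]
        if len(value_cols) != N_SAMPLES:
            raise ValueError(
                f"ensemble CSV has {len(value_cols)} sample columns, expected {N_SAMPLES}"
            )
        subjects = list(dict.fromkeys(df["subject_id"].astype(str)))
        channels = list(dict.fromkeys(df["channel"].astype(str)))
        visits = df["visit"].unique()
        if len(visits) != 1:
            raise ValueError("ensemble CSV must contain a single visit")
        data = np.full((len(subjects), len(channels), N_SAMPLES), np.nan)
        s_index = {s: i for i, s in enumerate(subjects)}
        c_index = {c: i for i, c in enumerate(channels)}
        for _, row in df.iterrows():
            data[s_index[str(row["subject_id"])], c_index[str(row["channel"])]] = (
                row[value_cols].to_numpy(dtype=float)
            )
        if np.isnan(data).any():
            raise ValueError("ensemble CSV missing subject/channel combinations")
        return cls(
            subjects=subjects,
            channels=channels,
            data=data,
            mass_kg=None if mass_kg is None else np.array([mass_kg[s] for s in subjects]),
            height_m=None if height_m is None else np.array([height_m[s] for s in subjects]),
            visit=str(visits[0]),
        )


# --- long trial CSV --------------------------------------------------------

def write_trials_csv(
    path: str | Path,
    subjects: Sequence[str],
    channels: Sequence[str],
    trials: np.ndarray,
    visit: str = "pre",
) -> None:
    """Write a (subjects x channels x trials x 101) array as a long trial CSV."""
    n_s, n_c, n_t, n_p = trials.shape
    if n_p != N_SAMPLES:
        raise ValueError("trial curves must have 101 samples")
    subj = np.repeat(list(subjects), n_c * n_t * n_p)
    chan = np.tile(np.repeat(list(channels), n_t * n_p), n_s)
    tr = np.tile(np.repeat(np.arange(n_t), n_p), n_s * n_c)
    ti = np.tile(np.arange(n_p), n_s * n_c * n_t)
    pd.DataFrame(
        {
            "subject_id": subj,
            "visit": visit,
            "channel": chan,
            "trial": tr,
            "t_index": ti,
            "value": trials.ravel(),
        }
    ).to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> dict[tuple[str, str], list[Trial]]:
    """Read a long trial CSV into per-(subject, channel) lists of trials."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"subject_id", "visit", "channel", "trial", "t_index", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"trial CSV missing columns {required - set(df.columns)}")
    if df["value"].isna().any():
        raise ValueError("trial CSV contains missing values")
    out: dict[tuple[str, str], list[Trial]] = {}
    grouped = df.sort_values(["subject_id", "channel", "trial", "t_index"]).groupby(
        ["subject_id", "channel", "trial"], sort=False
    )
    for (subj, chan, _), g in grouped:
        out.setdefault((str(subj), str(chan)), []).append(
            Trial(
                subject_id=str(subj),
                channel=str(chan),
                samples=g["value"].to_numpy(dtype=float),
                phase=CHANNEL_PHASE.get(str(chan), "cycle"),
                units=CHANNEL_UNITS.get(str(chan), ""),
            )
        )
    return out
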