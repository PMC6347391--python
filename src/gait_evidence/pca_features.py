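"""Per-channel PCA of gait waveforms and the osteoarthritis-low sign convention.

Each waveform channel is decomposed separately: the subject-by-sample matrix
is centred on its pointwise mean curve and the leading eigenvectors of the
sample covariance are taken as modes of variation.  A subject's PC score is
the projection of their centred curve onto a mode.  With the default three
components per channel and 23 channels, the study design yields 69 discrete
variables per subject.

Sign conventions: eigenvector signs from the decomposition are first fixed so
the largest-magnitude component of each eigenvector is positive (removes
solver-dependent ambiguity); then, for ease of interpretation, any column
whose osteoarthritic training mean exceeds the control mean is negated
(eigenvector and scores together), so a low score always points toward
osteoarthritic function.  Covariance (not correlation) PCA is used: curves
within a channel share units, and no per-sample standardization is applied
unless requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import N_SAMPLES
from .waveform_io import WaveformSet

OA, NP_GROUP = "OA", "NP"


def feature_label(channel: str, pc: int) -> str:
    """Flat column label for a (channel, PC index) feature, e.g. 'Vertical force_PC1'."""
    return f"{channel}_PC{pc}"


def parse_feature_label(label: str) -> tuple[str, int]:
    channel, pc = label.rsplit("_PC", 1)
    return channel, int(pc)


@dataclass
class PCModel:
    """Fitted principal-component basis for one waveform channel."""

    channel: str
    mean_curve: np.ndarray  # (101,)
    eigenvectors: np.ndarray  # (k, 101), orthonormal rows
    eigenvalues: np.ndarray  # (k,), descending
    variance_fraction: np.ndarray  # (k,), in [0, 1]
    sign_flipped: np.ndarray = field(default=None)  # (k,) bool

    def __post_init__(self) -> None:
        self.mean_curve = np.asarray(self.mean_curve, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_fraction = np.asarray(self.variance_fraction, dtype=float)
        if self.sign_flipped is None:
            self.sign_flipped = np.zeros(len(self.eigenvalues), dtype=bool)
        self.sign_flipped = np.asarray(self.sign_flipped, dtype=bool)
        k = self.eigenvectors.shape[0]
        if self.mean_curve.shape != (N_SAMPLES,) or self.eigenvectors.shape != (k, N_SAMPLES):
            raise ValueError("PCModel curves must have 101 samples")
        gram = self.eigenvectors @ self.eigenvectors.T
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("eigenvectors must be orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be descending")
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be nonnegative")

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[0]

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "mean_curve": self.mean_curve.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "sign_flipped": self.sign_flipped.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PCModel":
        return cls(
            channel=d["channel"],
            mean_curve=np.array(d["mean_curve"]),
            eigenvectors=np.array(d["eigenvectors"]),
            eigenvalues=np.array(d["eigenvalues"]),
            variance_fraction=np.array(d["variance_fraction"]),
            sign_flipped=np.array(d["sign_flipped"], dtype=bool),
        )


def save_models(models: Sequence[PCModel], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([m.to_dict() for m in models], sort_keys=True), encoding="utf-8"
    )


def load_models(path: str | Path) -> list[PCModel]:
    return [PCModel.from_dict(d) for d in json.loads(Path(path).read_text(encoding="utf-8"))]


def _fix_eigenvector_signs(components: np.ndarray) -> np.ndarray:
    """Make the largest-|.| entry of each eigenvector positive (platform-stable)."""
    out = components.copy()
    for j in range(out.shape[0]):
        i = int(np.argmax(np.abs(out[j])))
        if out[j, i] < 0:
            out[j] = -out[j]
    return out


def fit_pca(
    training: WaveformSet,
    labels: Mapping[str, str] | pd.Series,
    n_components: int = 3,
    standardize: bool = False,
) -> tuple[list[PCModel], pd.DataFrame]:
    """Fit per-channel PCA on the pooled training cohort and score it.

    Returns the fitted models (sign convention already applied using
    ``labels``) and the training :class:`~pandas.DataFrame` of PC scores
    (rows = subjects, columns = flat (channel, PC) labels).

    Requires at least ``n_components + 1`` subjects and both class labels
    present; post-operative data must be projected with these models, never
    refit.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    n = training.n_subjects
    if n < max(4, n_components + 1):
        raise ValueError(f"need at least {max(4, n_components + 1)} training subjects, got {n}")
    present = set(labels.reindex(training.subjects))
    if not {OA, NP_GROUP} <= present:
        raise ValueError("training labels must include both OA and NP subjects")

    models: list[PCModel] = []
    score_blocks: list[np.ndarray] = []
    columns: list[str] = []
    for ci, channel in enumerate(training.channels):
        x = training.data[:, ci, :]
        mean_curve = x.mean(axis=0)
        xc = x - mean_curve
        if standardize:
            sd = xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            xc = xc / sd
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
        eigvals_all = s**2 / (n - 1)
        total = float(eigvals_all.sum())
        comp = _fix_eigenvector_signs(vt[:n_components])
        eigvals = eigvals_all[:n_components]
        # guard: numerically-zero total variance (identical curves) -> no shares
        tiny = 1e-12 * max(1.0, float(np.mean(mean_curve**2)))
        varfrac = eigvals / total if total > tiny else np.zeros(n_components)
        models.append(
            PCModel(
                channel=channel,
                mean_curve=mean_curve,
                eigenvectors=comp,
                eigenvalues=eigvals,
                variance_fraction=varfrac,
            )
        )
        score_blocks.append(xc @ comp.T)
        columns += [feature_label(channel, j + 1) for j in range(n_components)]

    scores = pd.DataFrame(
        np.hstack(score_blocks), index=list(training.subjects), columns=columns
    )
    return apply_sign_convention(models, scores, labels)


def apply_sign_convention(
    models: Sequence[PCModel],
    scores: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
) -> tuple[list[PCModel], pd.DataFrame]:
    """Negate columns whose OA training mean exceeds the NP training mean.

    Eigenvector and scores are negated together and the flip recorded, so
    afterwards every column has OA mean <= NP mean.  Idempotent: a second
    application changes nothing.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    y = labels.reindex(scores.index)
    scores = scores.copy()
    models = [
        PCModel(
            channel=m.channel,
            mean_curve=m.mean_curve.copy(),
            eigenvectors=m.eigenvectors.copy(),
            eigenvalues=m.eigenvalues.copy(),
            variance_fraction=m.variance_fraction.copy(),
            sign_flipped=m.sign_flipped.copy(),
        )
        for m in models
    ]
    by_channel = {m.channel: m for m in models}
    for col in scores.columns:
        channel, pc = parse_feature_label(col)
        oa_mean = scores.loc[y == OA, col].mean()
        np_mean = scores.loc[y == NP_GROUP, col].mean()
        if oa_mean > np_mean:
            scores[col] = -scores[col]
            m = by_channel[channel]
            m.eigenvectors[pc - 1] = -m.eigenvectors[pc - 1]
            m.sign_flipped[pc - 1] = ~m.sign_flipped[pc - 1]
    return models, scores


def project(models: Sequence[PCModel], data: WaveformSet) -> pd.DataFrame:
    """Project a cohort onto fitted models, returning the PC-score matrix.

    The stored (possibly sign-flipped) eigenvectors are used directly, so
    projecting the training set reproduces the training scores exactly.
    """
    missing = [m.channel for m in models if m.channel not in data.channels]
    if missing:
        raise ValueError(f"data is missing channels required by the models: {missing}")
    blocks, columns = [], []
    for m in models:
        ci = data.channels.index(m.channel)
        xc = data.data[:, ci, :] - m.mean_curve
        blocks.append(xc @ m.eigenvectors.T)
        columns += [feature_label(m.channel, j + 1) for j in range(m.n_components)]
    return pd.DataFrame(np.hstack(blocks), index=list(data.subjects), columns=columns)


def reconstruct_single_component(model: PCModel, pc_index: int, score: float) -> np.ndarray:
    """Mean curve plus a single mode scaled by ``score`` (101 samples)."""
    if not 1 <= pc_index <= model.n_components:
        raise ValueError(f"pc_index must be in 1..{model.n_components}")
    return model.mean_curve + score * model.eigenvectors[pc_index - 1]


def representative_extremes(
    model: PCModel,
    pc_index: int,
    training_scores: Sequence[float],
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Single-component reconstructions at robust low/high training scores.

    Defaults to the 5th and 95th percentiles of the observed score
    distribution — symmetric robust extremes used to visualize the waveform
    feature each component represents.
    """
    lo, hi = np.percentile(np.asarray(training_scores, dtype=float), percentiles)
    return (
        reconstruct_single_component(model, pc_index, lo),
        reconstruct_single_component(model, pc_index, hi),
    )
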