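"""Synthetic multi-channel gait cohorts with a known low-dimensional structure.

The study's motion-capture data are not deposited, so every downstream stage
is exercised on cohorts built to have the *published statistical structure*:
each channel's ensemble curve is a channel mean curve plus three orthonormal
cosine modes weighted by per-subject scores, and for the 18 retained
(channel, PC) features those scores are drawn from group-specific Gaussians
whose means and SDs are the printed pre-operative, post-operative and
control values.  Walking trials add white noise around the subject's
ensemble curve; clinical metadata (body mass, height, 12-item knee-score
items) are drawn from distributions calibrated to the published group
summaries.

Printed location/scale pairs flagged as median (IQR) in the source table are
deliberately treated as Gaussian mean/SD here: the generator's role is
structural, not distributional replication.

Score scales for (channel, PC) columns outside the retained 18 are zero-mean
with SDs (9, 5, 1.5) by component index, chosen so that within every channel
the three generating-mode score variances are strictly descending — the
condition under which fitted PCA component order matches generating-mode
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import DEFAULT_CHANNELS, N_SAMPLES
from .pca_features import feature_label
from .waveform_io import WaveformSet, write_trials_csv

OA, NP_GROUP = "OA", "NP"

#: zero-mean score SD per PC index for columns without a printed effect
NOISE_SCORE_SDS = (9.0, 5.0, 1.5)

# Retained features: (channel, pc, mean_oa_pre, sd_oa_pre, mean_oa_post,
# sd_oa_post, mean_np, sd_np) in PC-score units.
_DEFAULT_EFFECTS = [
    ("Hip flexion angle", 1, -3.71, 11.68, -6.99, 11.72, 6.98, 6.14),
    ("Hip adduction angle", 2, -2.33, 2.77, -1.67, 2.37, 2.58, 2.01),
    ("Hip transverse angle", 2, -1.37, 1.93, 0.11, 1.72, 1.46, 1.63),
    ("Knee flexion angle", 2, -3.59, 3.72, -1.17, 4.27, 3.64, 3.26),
    ("Hip flexion moment", 2, -3.63, 3.22, -1.91, 3.85, 3.64, 3.91),
    ("Hip adduction moment", 2, -4.44, 3.06, -2.48, 2.32, 4.56, 2.10),
    ("Hip transverse moment", 1, -4.17, 7.81, -4.64, 5.39, 4.71, 3.93),
    ("Knee flexion moment", 1, -3.19, 8.41, -2.87, 6.07, 3.60, 3.84),
    ("Knee flexion moment", 2, -3.90, 3.13, -1.94, 3.83, 3.88, 3.79),
    ("Knee adduction moment", 2, -2.81, 2.08, -2.19, 1.67, 2.82, 2.59),
    ("Knee transverse moment", 1, -4.37, 7.54, -4.27, 5.03, 4.94, 3.86),
    ("Knee transverse moment", 2, -2.78, 3.00, -1.32, 3.22, 2.52, 3.24),
    ("Ankle dorsiflexion moment", 2, -4.36, 4.44, -0.96, 5.29, 4.54, 3.70),
    # pre-TKR scale printed with a spurious minus sign in the source; 2.34 used
    ("Ankle transverse moment", 3, -2.44, 2.34, -1.26, 1.74, 2.09, 2.70),
    ("Anteroposterior force", 1, -6.56, 4.82, -2.17, 5.25, 6.71, 3.91),
    ("Mediolateral force", 2, -2.03, 2.28, -0.04, 2.17, 2.08, 2.03),
    ("Vertical force", 1, -6.54, 3.68, -2.76, 4.12, 7.16, 3.45),
    ("AP position of COP", 2, -3.23, 3.63, -0.28, 5.12, 3.22, 4.07),
]

# Published clinical calibration targets: (total, pain %, function %) means.
_OKS_TARGETS = {"pre": (19.5, 27.5, 45.3), "post": (36.0, 82.1, 67.5), "np": (48.0, 100.0, 100.0)}
_FUNCTION_ITEMS = (2, 3, 7, 11, 12)  # 1-indexed questionnaire items
_BMI = {OA: (32.5, 6.5), NP_GROUP: (24.3, 3.7)}  # kg/m^2, mean (SD)


@dataclass(frozen=True)
class EffectSpec:
    """Group score means/SDs for one retained (channel, PC) feature."""

    feature_id: tuple[str, int]
    mean_oa_pre: float
    sd_oa_pre: float
    mean_oa_post: float
    sd_oa_post: float
    mean_np: float
    sd_np: float

    def __post_init__(self) -> None:
        if min(self.sd_oa_pre, self.sd_oa_post, self.sd_np) <= 0:
            raise ValueError(f"all SDs must be positive for {self.feature_id}")


def effects_for_channels(
    effects: list[EffectSpec], channels: list[str]
) -> list[EffectSpec]:
    """Restrict an effect-spec list to the channels actually simulated."""
    return [e for e in effects if e.feature_id[0] in channels]


def default_effect_spec() -> list[EffectSpec]:
    """The 18 retained biomechanical features with their published group stats."""
    return [
        EffectSpec((c, pc), m_pre, s_pre, m_post, s_post, m_np, s_np)
        for c, pc, m_pre, s_pre, m_post, s_post, m_np, s_np in _DEFAULT_EFFECTS
    ]


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort draw."""

    n_oa: int = 30
    n_np: int = 30
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    modes_per_channel: int = 3
    effect_specs: list[EffectSpec] = field(default_factory=default_effect_spec)
    trial_noise_sd: float = 1.0
    trials_per_subject: int = 6
    paired_correlation: float = 0.5
    noise_score_sds: tuple[float, ...] = NOISE_SCORE_SDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_oa < 2 or self.n_np < 2:
            raise ValueError("need at least 2 subjects per group")
        if not self.channels:
            raise ValueError("channel list must be non-empty")
        if self.trials_per_subject < 3:
            raise ValueError("need at least 3 trials per subject")
        if not -1.0 <= self.paired_correlation <= 1.0:
            raise ValueError("paired_correlation must lie in [-1, 1]")
        if self.trial_noise_sd < 0:
            raise ValueError("trial_noise_sd must be nonnegative")
        if len(self.noise_score_sds) < self.modes_per_channel:
            raise ValueError("need a noise score SD per mode")
        unknown = [e.feature_id for e in self.effect_specs if e.feature_id[0] not in self.channels]
        if unknown:
            raise ValueError(f"effect specs reference unknown channels: {unknown}")
        bad_pc = [
            e.feature_id
            for e in self.effect_specs
            if not 1 <= e.feature_id[1] <= self.modes_per_channel
        ]
        if bad_pc:
            raise ValueError(f"effect specs reference PCs out of range: {bad_pc}")


@dataclass
class SyntheticCohort:
    """A generated cohort: trials, ensemble waveforms, true scores, metadata."""

    waveforms: WaveformSet
    trials: np.ndarray  # (n_subjects, n_channels, trials_per_subject, 101)
    true_scores: pd.DataFrame
    metadata: pd.DataFrame

    @property
    def labels(self) -> pd.Series:
        return self.metadata.set_index("subject_id")["group"]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        visit = self.waveforms.visit
        self.metadata.to_csv(out / f"metadata_{visit}.csv", index=False)
        self.true_scores.to_csv(out / f"true_scores_{visit}.csv", index_label="subject_id")
        self.waveforms.to_csv(out / f"ensembles_{visit}.csv")
        write_trials_csv(
            out / f"trials_{visit}.csv",
            self.waveforms.subjects,
            self.waveforms.channels,
            self.trials,
            visit=visit,
        )


def cosine_modes(n_modes: int = 3, n_points: int = N_SAMPLES) -> np.ndarray:
    """Orthonormalized cosine family over the 101-sample grid, rows = modes."""
    t = np.arange(n_points)
    raw = np.stack(
        [np.cos((j + 1) * np.pi * t / (n_points - 1)) for j in range(n_modes)], axis=1
    )
    q, r = np.linalg.qr(raw)
    q = q * np.sign(np.diag(r))  # keep each mode aligned with its cosine seed
    return q.T


def _column_params(spec: CohortSpec, visit: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-column (mu, sd) arrays for OA (row 0) and NP (row 1) at a visit."""
    effects = {e.feature_id: e for e in spec.effect_specs}
    cols, mu, sd = [], [], []
    for channel in spec.channels:
        for pc in range(1, spec.modes_per_channel + 1):
            cols.append(feature_label(channel, pc))
            e = effects.get((channel, pc))
            if e is None:
                s = spec.noise_score_sds[pc - 1]
                mu.append([0.0, 0.0])
                sd.append([s, s])
            elif visit == "pre":
                mu.append([e.mean_oa_pre, e.mean_np])
                sd.append([e.sd_oa_pre, e.sd_np])
            else:
                mu.append([e.mean_oa_post, e.mean_np])
                sd.append([e.sd_oa_post, e.sd_np])
    return cols, np.array(mu).T, np.array(sd).T  # (2, n_cols)


def generate_feature_scores(
    effect_specs: list[EffectSpec],
    n_oa: int,
    n_np: int,
    rng: np.random.Generator,
    visit: str = "pre",
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the retained-feature score table directly (no waveform synthesis).

    Used when only the score-level structure matters (classifier studies);
    returns the subjects-by-features table and the group labels.
    """
    cols = [feature_label(*e.feature_id) for e in effect_specs]
    if visit == "pre":
        mu = np.array([[e.mean_oa_pre, e.mean_np] for e in effect_specs]).T
        sd = np.array([[e.sd_oa_pre, e.sd_np] for e in effect_specs]).T
    else:
        mu = np.array([[e.mean_oa_post, e.mean_np] for e in effect_specs]).T
        sd = np.array([[e.sd_oa_post, e.sd_np] for e in effect_specs]).T
    oa = mu[0] + sd[0] * rng.standard_normal((n_oa, len(cols)))
    np_ = mu[1] + sd[1] * rng.standard_normal((n_np, len(cols)))
    subjects = [f"OA{i + 1:02d}" for i in range(n_oa)] + [f"NP{i + 1:02d}" for i in range(n_np)]
    scores = pd.DataFrame(np.vstack([oa, np_]), index=subjects, columns=cols)
    labels = pd.Series([OA] * n_oa + [NP_GROUP] * n_np, index=subjects)
    return scores, labels


def _oks_item_probabilities(visit_key: str) -> np.ndarray:
    """Per-item binomial(4, p) success probabilities, calibrated on totals.

    Each item is drawn Binomial(4, p) with subscale-specific p taken from the
    published subscale percentages, then rescaled so the expected 12-item
    total matches the published group total (the printed total and subscale
    percentages are not exactly mutually consistent; the total wins).
    """
    total, pain_pct, function_pct = _OKS_TARGETS[visit_key]
    p = np.empty(12)
    for i in range(12):
        p[i] = function_pct / 100.0 if (i + 1) in _FUNCTION_ITEMS else pain_pct / 100.0
    expected = 4.0 * p.sum()
    if expected > 0:
        p = np.clip(p * (total / expected), 0.0, 1.0)
    return p


def _draw_metadata(
    subjects: list[str],
    groups: list[str],
    visit: str,
    rng: np.random.Generator,
    mass_kg: np.ndarray | None = None,
    height_m: np.ndarray | None = None,
) -> pd.DataFrame:
    n = len(subjects)
    if height_m is None:
        height_m = np.clip(1.70 + 0.09 * rng.standard_normal(n), 1.45, 2.00)
    if mass_kg is None:
        bmi = np.array(
            [
                np.clip(_BMI[g][0] + _BMI[g][1] * rng.standard_normal(), 16.0, 55.0)
                for g in groups
            ]
        )
        mass_kg = bmi * height_m**2
    items = np.empty((n, 12), dtype=int)
    for i, g in enumerate(groups):
        key = "np" if g == NP_GROUP else visit
        items[i] = rng.binomial(4, _oks_item_probabilities(key))
    meta = pd.DataFrame(
        {
            "subject_id": subjects,
            "group": groups,
            "visit": visit,
            "mass_kg": np.round(mass_kg, 3),
            "height_m": np.round(height_m, 3),
        }
    )
    for q in range(12):
        meta[f"oks_q{q + 1}"] = items[:, q]
    return meta


def _mean_curves(channels: list[str], rng: np.random.Generator) -> np.ndarray:
    """Smooth channel mean curves: random low-order cosine series."""
    t = np.arange(N_SAMPLES) / (N_SAMPLES - 1)
    basis = np.stack([np.cos(j * np.pi * t) for j in range(5)])
    coeffs = 5.0 * rng.standard_normal((len(channels), 5))
    return coeffs @ basis


def _assemble_cohort(
    spec: CohortSpec,
    scores: np.ndarray,
    cols: list[str],
    subjects: list[str],
    groups: list[str],
    visit: str,
    mean_curves: np.ndarray,
    modes: np.ndarray,
    noise_rng: np.random.Generator,
    meta: pd.DataFrame,
) -> SyntheticCohort:
    n_s, n_c, k = len(subjects), len(spec.channels), spec.modes_per_channel
    score_cube = scores.reshape(n_s, n_c, k)
    ensembles = mean_curves[None, :, :] + np.einsum("sck,kt->sct", score_cube, modes)
    trials = ensembles[:, :, None, :] + spec.trial_noise_sd * noise_rng.standard_normal(
        (n_s, n_c, spec.trials_per_subject, N_SAMPLES)
    )
    observed = trials.mean(axis=2)
    waveforms = WaveformSet(
        subjects=subjects,
        channels=list(spec.channels),
        data=observed,
        mass_kg=meta["mass_kg"].to_numpy(),
        height_m=meta["height_m"].to_numpy(),
        visit=visit,
    )
    true_scores = pd.DataFrame(scores, index=subjects, columns=cols)
    return SyntheticCohort(waveforms=waveforms, trials=trials, true_scores=true_scores, metadata=meta)


def _subjects_and_groups(spec: CohortSpec) -> tuple[list[str], list[str]]:
    subjects = [f"OA{i + 1:02d}" for i in range(spec.n_oa)] + [
        f"NP{i + 1:02d}" for i in range(spec.n_np)
    ]
    groups = [OA] * spec.n_oa + [NP_GROUP] * spec.n_np
    return subjects, groups


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one synthetic cohort (OA at the pre-operative visit + controls).

    Identical ``spec.seed`` values produce bit-identical cohorts.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_curves, rng_scores, rng_noise, rng_meta, *_ = [
        np.random.default_rng(c) for c in ss.spawn(6)
    ]
    subjects, groups = _subjects_and_groups(spec)
    cols, mu, sd = _column_params(spec, "pre")
    group_row = np.array([0 if g == OA else 1 for g in groups])
    z = rng_scores.standard_normal((len(subjects), len(cols)))
    scores = mu[group_row] + sd[group_row] * z
    mean_curves = _mean_curves(spec.channels, rng_curves)
    modes = cosine_modes(spec.modes_per_channel)
    meta = _draw_metadata(subjects, groups, "pre", rng_meta)
    return _assemble_cohort(
        spec, scores, cols, subjects, groups, "pre", mean_curves, modes, rng_noise, meta
    )


def generate_paired_cohort(spec: CohortSpec) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Generate matched pre- and post-operative cohorts.

    The pre cohort holds OA subjects at the pre-operative visit plus the NP
    controls; the post cohort holds the *same* OA subjects (same identifiers,
    same anthropometrics) at the follow-up visit.  Per feature, each OA
    subject's (pre, post) scores are bivariate Gaussian with the stated
    visit-specific means/SDs and correlation ``spec.paired_correlation``.
    """
    rho = spec.paired_correlation
    ss = np.random.SeedSequence(spec.seed)
    rng_curves, rng_scores, rng_noise, rng_meta, rng_post_noise, rng_post_meta = [
        np.random.default_rng(c) for c in ss.spawn(6)
    ]
    subjects, groups = _subjects_and_groups(spec)
    oa_subjects = subjects[: spec.n_oa]
    cols, mu_pre, sd_pre = _column_params(spec, "pre")
    _, mu_post, sd_post = _column_params(spec, "post")
    group_row = np.array([0 if g == OA else 1 for g in groups])
    z = rng_scores.standard_normal((len(subjects), len(cols)))
    z_eps = rng_scores.standard_normal((spec.n_oa, len(cols)))
    scores_pre = mu_pre[group_row] + sd_pre[group_row] * z
    z_post = rho * z[: spec.n_oa] + np.sqrt(max(0.0, 1.0 - rho**2)) * z_eps
    scores_post = mu_post[0] + sd_post[0] * z_post

    mean_curves = _mean_curves(spec.channels, rng_curves)
    modes = cosine_modes(spec.modes_per_channel)
    meta_pre = _draw_metadata(subjects, groups, "pre", rng_meta)
    pre = _assemble_cohort(
        spec, scores_pre, cols, subjects, groups, "pre", mean_curves, modes, rng_noise, meta_pre
    )
    meta_post = _draw_metadata(
        oa_subjects,
        [OA] * spec.n_oa,
        "post",
        rng_post_meta,
        mass_kg=meta_pre["mass_kg"].to_numpy()[: spec.n_oa],
        height_m=meta_pre["height_m"].to_numpy()[: spec.n_oa],
    )
    post = _assemble_cohort(
        spec,
        scores_post,
        cols,
        oa_subjects,
        [OA] * spec.n_oa,
        "post",
        mean_curves,
        modes,
        rng_post_noise,
        meta_post,
    )
    return pre, post
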