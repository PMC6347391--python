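"""End-to-end orchestration: generate/load -> PCA -> rank -> train -> validate
-> follow-up projection -> belief trajectories -> statistics.

A run is fully described by a :class:`RunConfig` (one YAML file); all
randomness flows from the single root seed through named substreams (cohort
generation and the ranking split), so identical config + seed reproduces
byte-identical numeric artifacts.  The PCA basis and the classifier are fit
once on the pre-operative training set (surgical group + controls) and are
*frozen*: follow-up data are always projected and classified with the stored
models, never refit, and the run report records model checksums so any
accidental refit would be visible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .channels import DEFAULT_CHANNELS
from .dst import (
    ClassifierModel,
    classify,
    fit as fit_classifier,
    loo_accuracy,
    rank_features,
    simplex_coords,
)
from .pca_features import PCModel, fit_pca, project, save_models
from .stats_report import build_feature_table, clinical_table, rows_to_frame
from .synthetic import (
    CohortSpec,
    default_effect_spec,
    effects_for_channels,
    generate_paired_cohort,
)
from .waveform_io import WaveformSet


@dataclass
class RunConfig:
    """Every knob of a pipeline run, YAML-serializable."""

    mode: str = "synthetic"  # 'synthetic' or 'csv'
    seed: int = 0
    out_dir: str = "results/run"
    # synthetic-cohort knobs
    n_oa: int = 30
    n_np: int = 30
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    n_pcs: int = 3
    trial_noise_sd: float = 1.0
    trials_per_subject: int = 6
    paired_correlation: float = 0.5
    # csv-mode inputs: directory containing ensembles_{pre,post}.csv and
    # metadata_{pre,post}.csv as written by synthetic mode
    csv_dir: str | None = None
    # analysis knobs
    rank_top_n: int = 18
    evidence_a: float = 0.1
    evidence_b: float = 0.9
    refine: bool = False
    alpha: float = 0.05
    grf_divisor: str = "weight"

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_oa=self.n_oa,
            n_np=self.n_np,
            channels=list(self.channels),
            modes_per_channel=self.n_pcs,
            effect_specs=effects_for_channels(default_effect_spec(), list(self.channels)),
            trial_noise_sd=self.trial_noise_sd,
            trials_per_subject=self.trials_per_subject,
            paired_correlation=self.paired_correlation,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")


@dataclass
class RunReport:
    """Everything a reader needs to trace a run's reported numbers."""

    version: str
    config: dict
    retained_features: list[str]
    n_retained: int
    ranking_accuracy: dict
    loo_accuracy: float
    loo_correct: int
    n_training: int
    pca_checksum: str
    classifier_checksum: str
    n_significant_prepost: int
    n_significant_nppost: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def _belief_table(
    model: ClassifierModel, features: pd.DataFrame, truth: pd.Series | None
) -> pd.DataFrame:
    records = []
    for subj in features.index:
        boe = model.combined(features.loc[subj])
        x, y = simplex_coords(boe)
        records.append(
            {
                "subject_id": subj,
                "m_oa": boe.m_oa,
                "m_np": boe.m_np,
                "m_u": boe.m_u,
                "x": x,
                "y": y,
                "predicted": classify(boe),
                "true": None if truth is None else truth[subj],
            }
        )
    return pd.DataFrame.from_records(records).set_index("subject_id")


def classify_followup(
    model: ClassifierModel,
    pca_models: Sequence[PCModel],
    post_data: WaveformSet,
    truth: pd.Series | None = None,
) -> pd.DataFrame:
    """Project follow-up curves with the frozen PCA basis and classify with
    the frozen evidence model.  Nothing is refit."""
    scores = project(pca_models, post_data)
    missing = [f for f in model.features if f not in scores.columns]
    if missing:
        raise ValueError(f"follow-up projection lacks model features: {missing}")
    return _belief_table(model, scores[model.features], truth)


def _load_csv_cohort(csv_dir: Path) -> tuple[WaveformSet, WaveformSet, pd.DataFrame, pd.DataFrame]:
    meta_pre = pd.read_csv(csv_dir / "metadata_pre.csv")
    meta_post = pd.read_csv(csv_dir / "metadata_post.csv")
    pre = WaveformSet.from_csv(csv_dir / "ensembles_pre.csv")
    post = WaveformSet.from_csv(csv_dir / "ensembles_post.csv")
    return pre, post, meta_pre, meta_post


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage and write per-stage artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: data -----------------------------------------------------
    if config.mode == "synthetic":
        pre_cohort, post_cohort = generate_paired_cohort(config.cohort_spec())
        pre_waves, post_waves = pre_cohort.waveforms, post_cohort.waveforms
        meta_pre, meta_post = pre_cohort.metadata, post_cohort.metadata
        meta_pre.to_csv(out / "metadata_pre.csv", index=False)
        meta_post.to_csv(out / "metadata_post.csv", index=False)
        pre_waves.to_csv(out / "ensembles_pre.csv")
        post_waves.to_csv(out / "ensembles_post.csv")
    elif config.mode == "csv":
        if config.csv_dir is None:
            raise ValueError("csv mode requires csv_dir")
        pre_waves, post_waves, meta_pre, meta_post = _load_csv_cohort(Path(config.csv_dir))
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    labels = meta_pre.set_index("subject_id")["group"]

    # --- stage 2: PCA features --------------------------------------------
    pca_models, features_pre = fit_pca(pre_waves, labels, n_components=config.n_pcs)
    features_post = project(pca_models, post_waves)
    save_models(pca_models, out / "pca_models.json")
    pca_checksum = _sha256((out / "pca_models.json").read_text(encoding="utf-8"))
    features_pre.to_csv(out / "features_pre.csv", index_label="subject_id")
    features_post.to_csv(out / "features_post.csv", index_label="subject_id")

    # --- stage 3: split-half ranking ---------------------------------------
    rank_seed = np.random.SeedSequence(entropy=config.seed, spawn_key=(101,))
    ranking = rank_features(features_pre, labels, seed=rank_seed, top_n=config.rank_top_n)
    ranking.accuracy.to_csv(out / "ranking.csv", index_label="feature_id")
    retained = ranking.retained
    features_pre_sel = features_pre[retained]
    features_post_sel = features_post[retained]

    # --- stage 4: train + leave-one-out ------------------------------------
    model = fit_classifier(
        features_pre_sel, labels, A=config.evidence_a, B=config.evidence_b, refine=config.refine
    )
    model_json = model.to_json()
    (out / "classifier.json").write_text(model_json, encoding="utf-8")
    classifier_checksum = _sha256(model_json)
    acc, loo_beliefs = loo_accuracy(
        features_pre_sel, labels, A=config.evidence_a, B=config.evidence_b
    )
    loo_beliefs.to_csv(out / "beliefs_loo_pre.csv")

    # --- stage 5: frozen-model beliefs, pre and follow-up -------------------
    beliefs_pre = _belief_table(model, features_pre_sel, labels)
    beliefs_pre.to_csv(out / "beliefs_train_pre.csv")
    beliefs_post = classify_followup(
        model, pca_models, post_waves, truth=labels.reindex(post_waves.subjects)
    )
    beliefs_post.to_csv(out / "beliefs_post.csv")
    if _sha256(model.to_json()) != classifier_checksum:
        raise RuntimeError("classifier mutated during follow-up classification")

    # --- stage 6: belief trajectories (recovery arrows) ---------------------
    oa_subjects = [s for s in post_waves.subjects]
    traj = pd.DataFrame(
        {
            "x_pre": beliefs_pre.loc[oa_subjects, "x"],
            "y_pre": beliefs_pre.loc[oa_subjects, "y"],
            "x_post": beliefs_post.loc[oa_subjects, "x"],
            "y_post": beliefs_post.loc[oa_subjects, "y"],
        }
    )
    traj["dx"] = traj["x_post"] - traj["x_pre"]
    traj["dy"] = traj["y_post"] - traj["y_pre"]
    traj.to_csv(out / "trajectories.csv", index_label="subject_id")

    # --- stage 7: statistics ------------------------------------------------
    oa_pre_scores = features_pre_sel.loc[oa_subjects]
    np_scores = features_pre_sel.loc[labels.reindex(features_pre_sel.index) == "NP"]
    stats_rows = build_feature_table(
        oa_pre_scores, features_post_sel.loc[oa_subjects], np_scores, alpha=config.alpha
    )
    stats_frame = rows_to_frame(stats_rows)
    stats_frame.to_csv(out / "stats_features.csv")
    clinical = clinical_table(meta_pre, meta_post)
    clinical.to_csv(out / "stats_clinical.csv")

    report = RunReport(
        version=__version__,
        config=asdict(config),
        retained_features=retained,
        n_retained=len(retained),
        ranking_accuracy={
            f: [float(ranking.accuracy.loc[f, "half1"]), float(ranking.accuracy.loc[f, "half2"])]
            for f in retained
        },
        loo_accuracy=acc,
        loo_correct=int(round(acc * len(features_pre_sel))),
        n_training=len(features_pre_sel),
        pca_checksum=pca_checksum,
        classifier_checksum=classifier_checksum,
        n_significant_prepost=int(stats_frame["sig_prepost"].sum()),
        n_significant_nppost=int(stats_frame["sig_nppost"].sum()),
    )
    (out / "run_report.json").write_text(report.to_json(), encoding="utf-8")
    return report
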