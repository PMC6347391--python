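"""Dempster-Shafer evidence classifier for two-class gait assessment.

The frame of discernment has two hypotheses: osteoarthritic (OA) and
non-pathological (NP) function.  Each biomechanical feature value is mapped
to a *body of evidence* — a mass assignment (m_OA, m_NP, m_U) over {OA},
{NP} and the whole frame (the uncertainty mass) — via a sigmoid confidence
factor and a linear, truncated mass construction:

    cf    = 1 / (1 + exp(-k (v - theta)))
    m_OA  = max(0, B (cf - A) / (1 - A))
    m_NP  = max(0, B (1 - cf - A) / (1 - A))      (mirror of m_OA, cf -> 1-cf)
    m_U   = 1 - m_OA - m_NP

``A`` in [0, 0.5) sets the confidence-factor zero-crossing of each committed
mass and ``B`` in (0, 1] caps the committed mass (so uncertainty never falls
below 1 - B for a single feature).  Bodies of evidence are fused with
Dempster's rule of combination; a subject is assigned OA when the combined
m_OA strictly exceeds m_NP (exact ties are reported as unclassified).

Training is deterministic moment matching: per feature, ``theta`` is the
midpoint of the class means and ``|k| = 4 / |class mean difference|``, which
puts the confidence factor at ~0.88 at each class mean; the sign of ``k``
makes higher confidence point toward OA (negative ``k`` under the
osteoarthritis-low score convention).  An optional numerical refinement of
the shared (A, B) pair is available.

Belief triples are visualized on a barycentric simplex: NP vertex at (0, 0),
OA at (1, 0), uncertainty at (1/2, sqrt(3)/2); the locus m_OA = m_NP is the
vertical median x = 1/2 (the decision boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

OA, NP_GROUP = "OA", "NP"
UNCLASSIFIED = "unclassified"

_SUM_TOL = 1e-10


class TotalConflictError(ValueError):
    """Dempster combination is undefined: the two bodies fully contradict."""


@dataclass(frozen=True)
class BodyOfEvidence:
    """Mass assignment over {OA}, {NP} and the frame {OA, NP} (uncertainty)."""

    m_oa: float
    m_np: float
    m_u: float

    def __post_init__(self) -> None:
        masses = (self.m_oa, self.m_np, self.m_u)
        if min(masses) < -_SUM_TOL:
            raise ValueError(f"negative mass in {masses}")
        if abs(sum(masses) - 1.0) > _SUM_TOL:
            raise ValueError(f"masses must sum to 1, got {sum(masses)!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.m_oa, self.m_np, self.m_u])


VACUOUS = BodyOfEvidence(0.0, 0.0, 1.0)


@dataclass(frozen=True)
class FeatureEvidenceParams:
    """Sigmoid slope/offset and mass-construction controls for one feature."""

    k: float
    theta: float
    A: float = 0.1
    B: float = 0.9

    def __post_init__(self) -> None:
        if self.k == 0:
            raise ValueError("sigmoid slope k must be nonzero")
        if not 0.0 <= self.A < 0.5:
            raise ValueError("A must lie in [0, 0.5)")
        if not 0.0 < self.B <= 1.0:
            raise ValueError("B must lie in (0, 1]")


def confidence_factor(value: float, params: FeatureEvidenceParams) -> float:
    """Sigmoid evidential confidence toward OA: 1/(1+exp(-k (v - theta)))."""
    return float(expit(params.k * (np.asarray(value, dtype=float) - params.theta)))


def boe_from_feature(value: float, params: FeatureEvidenceParams) -> BodyOfEvidence:
    """Map one feature value to a body of evidence (see module docstring)."""
    cf = confidence_factor(value, params)
    scale = params.B / (1.0 - params.A)
    m_oa = max(0.0, scale * (cf - params.A))
    m_np = max(0.0, scale * (1.0 - cf - params.A))
    return BodyOfEvidence(m_oa, m_np, 1.0 - m_oa - m_np)


def combine(b1: BodyOfEvidence, b2: BodyOfEvidence) -> BodyOfEvidence:
    """Dempster's rule of combination for the two-hypothesis frame.

    Conflict ``K = m1_OA m2_NP + m1_NP m2_OA``; compatible products are
    renormalized by ``1 - K``.  ``K = 1`` (total conflict) is undefined and
    raises :class:`TotalConflictError`.
    """
    k_conflict = b1.m_oa * b2.m_np + b1.m_np * b2.m_oa
    if 1.0 - k_conflict <= _SUM_TOL:
        raise TotalConflictError("total conflict: combination undefined (K = 1)")
    z = 1.0 - k_conflict
    m_oa = (b1.m_oa * b2.m_oa + b1.m_oa * b2.m_u + b1.m_u * b2.m_oa) / z
    m_np = (b1.m_np * b2.m_np + b1.m_np * b2.m_u + b1.m_u * b2.m_np) / z
    m_u = (b1.m_u * b2.m_u) / z
    total = m_oa + m_np + m_u
    return BodyOfEvidence(m_oa / total, m_np / total, m_u / total)


def combine_all(boes: Sequence[BodyOfEvidence]) -> BodyOfEvidence:
    """Left fold of Dempster's rule; order-independent up to float tolerance."""
    if not boes:
        raise ValueError("need at least one body of evidence")
    return reduce(combine, boes)


def classify(b: BodyOfEvidence) -> str:
    """OA iff m_OA > m_NP, NP iff m_NP > m_OA, else the unclassified sentinel."""
    if b.m_oa > b.m_np:
        return OA
    if b.m_np > b.m_oa:
        return NP_GROUP
    return UNCLASSIFIED


def simplex_coords(b: BodyOfEvidence) -> tuple[float, float]:
    """Barycentric coordinates of a belief triple in the equilateral simplex.

    Vertices: NP -> (0, 0), OA -> (1, 0), uncertainty -> (1/2, sqrt(3)/2).
    Any triple with m_OA = m_NP lands on the vertical median x = 1/2.
    """
    x = b.m_oa + 0.5 * b.m_u
    y = (np.sqrt(3.0) / 2.0) * b.m_u
    return float(x), float(y)


@dataclass
class ClassifierModel:
    """Trained evidence classifier: one sigmoid/mass mapping per feature."""

    features: list[str]
    params: dict[str, FeatureEvidenceParams]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("classifier needs at least one feature")
        missing = [f for f in self.features if f not in self.params]
        if missing:
            raise ValueError(f"missing evidence params for features: {missing}")

    def subject_boes(self, row: Mapping[str, float]) -> list[BodyOfEvidence]:
        return [boe_from_feature(row[f], self.params[f]) for f in self.features]

    def combined(self, row: Mapping[str, float]) -> BodyOfEvidence:
        return combine_all(self.subject_boes(row))

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": self.features,
                "params": {
                    f: {"k": p.k, "theta": p.theta, "A": p.A, "B": p.B}
                    for f, p in self.params.items()
                },
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            features=list(d["features"]),
            params={f: FeatureEvidenceParams(**p) for f, p in d["params"].items()},
        )


def _as_labels(labels, index) -> pd.Series:
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    y = labels.reindex(index)
    if y.isna().any():
        raise ValueError("labels missing for some subjects")
    return y


def fit(
    features: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    A: float = 0.1,
    B: float = 0.9,
    refine: bool = False,
) -> ClassifierModel:
    """Train the classifier by deterministic moment matching.

    Features with exactly zero class-mean separation carry no direction and
    are dropped; training fails only if no feature separates at all.  With
    ``refine=True`` the shared (A, B) pair is additionally tuned by
    Nelder-Mead to minimize training misclassification plus the mean simplex
    distance to each subject's own-class vertex (the deterministic path is
    the default, so results are seed-free).
    """
    y = _as_labels(labels, features.index)
    for cls_name in (OA, NP_GROUP):
        if (y == cls_name).sum() < 2:
            raise ValueError(f"need at least 2 subjects of class {cls_name}")
    mu_oa = features.loc[y == OA].mean()
    mu_np = features.loc[y == NP_GROUP].mean()
    diff = mu_np - mu_oa
    kept = [f for f in features.columns if diff[f] != 0.0]
    if not kept:
        raise ValueError("zero class-mean separation on every feature")
    params = {
        f: FeatureEvidenceParams(
            k=float(-4.0 / diff[f]), theta=float((mu_oa[f] + mu_np[f]) / 2.0), A=A, B=B
        )
        for f in kept
    }
    model = ClassifierModel(features=kept, params=params)
    if refine:
        model = _refine_ab(model, features, y)
    return model


def _refine_ab(model: ClassifierModel, features: pd.DataFrame, y: pd.Series) -> ClassifierModel:
    vertices = {OA: np.array([1.0, 0.0]), NP_GROUP: np.array([0.0, 0.0])}

    def rebuild(a: float, b: float) -> ClassifierModel:
        return ClassifierModel(
            features=model.features,
            params={
                f: FeatureEvidenceParams(k=p.k, theta=p.theta, A=a, B=b)
                for f, p in model.params.items()
            },
        )

    def objective(ab: np.ndarray) -> float:
        a, b = ab
        if not (0.0 <= a < 0.5 and 0.0 < b <= 1.0):
            return 1e6
        m = rebuild(a, b)
        errors, dist = 0, 0.0
        for subj, row in features.iterrows():
            boe = m.combined(row)
            if classify(boe) != y[subj]:
                errors += 1
            dist += float(np.linalg.norm(np.array(simplex_coords(boe)) - vertices[y[subj]]))
        return errors / len(features) + dist / len(features)

    res = minimize(
        objective,
        x0=np.array([model.params[model.features[0]].A, model.params[model.features[0]].B]),
        method="Nelder-Mead",
        options={"maxiter": 60, "xatol": 1e-3, "fatol": 1e-4},
    )
    a, b = res.x
    a = float(np.clip(a, 0.0, 0.499))
    b = float(np.clip(b, 1e-3, 1.0))
    return rebuild(a, b)


def loo_accuracy(
    features: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    A: float = 0.1,
    B: float = 0.9,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validated accuracy and per-subject beliefs.

    For every subject the classifier is refit on the remaining n-1 subjects,
    the held-out subject's evidence is combined and classified.  Returns the
    fraction correct (exact belief ties count as incorrect) and a table of
    per-subject combined beliefs, simplex coordinates, prediction and truth.
    """
    y = _as_labels(labels, features.index)
    records = []
    correct = 0
    for subj in features.index:
        rest = features.drop(index=subj)
        model = fit(rest, y.drop(index=subj), A=A, B=B)
        boe = model.combined(features.loc[subj])
        pred = classify(boe)
        if pred == y[subj]:
            correct += 1
        x, ycoord = simplex_coords(boe)
        records.append(
            {
                "subject_id": subj,
                "m_oa": boe.m_oa,
                "m_np": boe.m_np,
                "m_u": boe.m_u,
                "x": x,
                "y": ycoord,
                "predicted": pred,
                "true": y[subj],
            }
        )
    beliefs = pd.DataFrame.from_records(records).set_index("subject_id")
    return correct / len(features), beliefs


def _single_feature_loo_correct(x: np.ndarray, is_oa: np.ndarray) -> float:
    """Fast exact single-feature LOO accuracy.

    With one feature, the combined belief is the feature's own body of
    evidence, and m_OA > m_NP iff cf > 1/2 iff k (x - theta) > 0 — so only
    the held-out class means are needed.  Equivalent to
    ``loo_accuracy(features[[f]], labels)[0]`` (cross-checked in the tests).
    """
    n = x.size
    n_oa = int(is_oa.sum())
    n_np = n - n_oa
    sum_oa = float(x[is_oa].sum())
    sum_np = float(x[~is_oa].sum())
    correct = 0
    for i in range(n):
        if is_oa[i]:
            if n_oa < 2:
                continue
            mu_oa = (sum_oa - x[i]) / (n_oa - 1)
            mu_np = sum_np / n_np
        else:
            if n_np < 2:
                continue
            mu_oa = sum_oa / n_oa
            mu_np = (sum_np - x[i]) / (n_np - 1)
        diff = mu_np - mu_oa
        if diff == 0.0:
            continue  # vacuous feature: tie, counts as incorrect
        theta = 0.5 * (mu_oa + mu_np)
        s = -(x[i] - theta) / diff  # sign of k (x - theta); >0 predicts OA
        pred_oa = s > 0
        if s != 0.0 and pred_oa == bool(is_oa[i]):
            correct += 1
    return correct / n


@dataclass
class RankingResult:
    """Split-half single-feature accuracies and the retained feature set."""

    accuracy: pd.DataFrame  # index features, columns ['half1', 'half2']
    retained: list[str]
    half_subjects: tuple[list[str], list[str]] = field(default_factory=tuple)


def rank_features(
    features: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    seed: int | np.random.SeedSequence = 0,
    top_n: int = 18,
) -> RankingResult:
    """Split-half feature ranking to curb over-fitting.

    Subjects are split into two class-stratified halves (seeded); within each
    half, every feature is scored by its single-feature leave-one-out
    accuracy; the retained set is the intersection of the two halves' top-N
    features.  Features tying with the N-th ranked accuracy are included
    (accuracies are exact multiples of 1/n, so ties are exact), which makes
    the retained set invariant to feature column order.
    """
    y = _as_labels(labels, features.index)
    rng = np.random.default_rng(seed)
    halves: tuple[list[str], list[str]] = ([], [])
    for cls_name in (OA, NP_GROUP):
        members = list(features.index[y == cls_name])
        if len(members) < 4:
            raise ValueError(f"need at least 4 subjects of class {cls_name} to split")
        order = rng.permutation(len(members))
        cut = (len(members) + 1) // 2
        halves[0].extend(members[i] for i in order[:cut])
        halves[1].extend(members[i] for i in order[cut:])
    for half in halves:
        if len(set(y[half])) < 2:
            raise ValueError("a split half lost one of the classes")

    acc = pd.DataFrame(index=features.columns, columns=["half1", "half2"], dtype=float)
    top_sets = []
    for hi, half in enumerate(halves):
        sub = features.loc[half]
        is_oa = (y[half] == OA).to_numpy()
        col = f"half{hi + 1}"
        for f in features.columns:
            acc.loc[f, col] = _single_feature_loo_correct(
                sub[f].to_numpy(dtype=float), is_oa
            )
        n_keep = min(top_n, len(features.columns))
        threshold = np.sort(acc[col].to_numpy())[::-1][n_keep - 1]
        top_sets.append({f for f in features.columns if acc.loc[f, col] >= threshold})

    retained = [f for f in features.columns if f in top_sets[0] & top_sets[1]]
    return RankingResult(accuracy=acc, retained=retained, half_subjects=(halves[0], halves[1]))
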