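"""Clinical scores and pre/post/control statistical comparisons.

Two contrast families are assembled per feature table: a paired pre- vs
post-operative contrast within the surgical group, and an unpaired contrast
of the post-operative group against the non-pathological controls.  Each
contrast passes through an explicit normality gate (Shapiro-Wilk at
alpha = 0.05 on the differences for the paired case, on each group for the
unpaired case): parametric branch (paired t / Welch t) when the gate passes,
otherwise Wilcoxon signed-rank / Mann-Whitney U.  P-values are
Bonferroni-adjusted within each contrast family separately (family size =
number of features), and a feature is flagged significant when the adjusted
p falls strictly below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SHAPIRO_ALPHA = 0.05

FUNCTION_ITEMS = (2, 3, 7, 11, 12)  # 1-indexed questionnaire items


def oks_subscales(items: Sequence[int]) -> tuple[int, float, float]:
    """Total, pain % and function % of a 12-item knee score (items 0-4 each).

    The function subscale sums items 2, 3, 7, 11 and 12 (max 20); the pain
    subscale sums the remaining seven items (max 28); both are expressed as
    percentages with 100 the best outcome.
    """
    items = np.asarray(items, dtype=float)
    if items.shape != (12,):
        raise ValueError("expected exactly 12 item scores")
    if np.any((items < 0) | (items > 4)) or np.any(items != np.round(items)):
        raise ValueError("each item score must be an integer in 0..4")
    function_mask = np.zeros(12, dtype=bool)
    function_mask[[q - 1 for q in FUNCTION_ITEMS]] = True
    function_sum = items[function_mask].sum()
    pain_sum = items[~function_mask].sum()
    return int(items.sum()), 100.0 * pain_sum / 28.0, 100.0 * function_sum / 20.0


def _is_normal(values: np.ndarray) -> bool:
    """Shapiro-Wilk gate; degenerate (constant) samples fail the gate."""
    if np.ptp(values) == 0.0:
        return False
    return stats.shapiro(values).pvalue > SHAPIRO_ALPHA


@dataclass
class CompareResult:
    """One contrast: chosen test, two-sided p, and a degeneracy flag."""

    test_name: str
    p_raw: float
    n: int
    degenerate: bool = False


def paired_compare(pre: Sequence[float], post: Sequence[float]) -> CompareResult:
    """Paired pre/post contrast: paired t when differences look normal, else
    Wilcoxon signed-rank.  All-zero differences return p = 1 with the
    degenerate flag set."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    if pre.size < 5:
        raise ValueError("need at least 5 pairs")
    diffs = post - pre
    if np.ptp(diffs) == 0.0 and diffs[0] == 0.0:
        return CompareResult("degenerate", 1.0, pre.size, degenerate=True)
    if _is_normal(diffs):
        p = stats.ttest_rel(post, pre).pvalue
        return CompareResult("paired-t", float(p), pre.size)
    p = stats.wilcoxon(post, pre).pvalue
    return CompareResult("wilcoxon-signed-rank", float(p), pre.size)


def unpaired_compare(a: Sequence[float], b: Sequence[float]) -> CompareResult:
    """Two-group contrast: Welch t when both groups look normal, else
    Mann-Whitney U (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 observations per group")
    if _is_normal(a) and _is_normal(b):
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        return CompareResult("t-test", float(p), a.size + b.size)
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0 and a[0] == b[0]:
        return CompareResult("degenerate", 1.0, a.size + b.size, degenerate=True)
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return CompareResult("mann-whitney", float(p), a.size + b.size)


def bonferroni_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment min(1, m p) and strict significance flags."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="bonferroni")
    flags = p_adj < alpha
    return p_adj, flags


@dataclass
class StatsRow:
    """Per-feature group summaries and both adjusted contrasts."""

    feature_id: str
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    np_mean: float
    np_sd: float
    test_prepost: str
    p_prepost_raw: float
    p_prepost_adj: float
    sig_prepost: bool
    test_nppost: str
    p_nppost_raw: float
    p_nppost_adj: float
    sig_nppost: bool


def build_feature_table(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    np_cohort: pd.DataFrame,
    alpha: float = 0.05,
) -> list[StatsRow]:
    """Per-feature statistics table (group summaries + two contrast families).

    ``pre`` and ``post`` must share subjects (paired by index) and all three
    tables must share the feature columns; rows come out in ``pre``'s column
    order.  Bonferroni families are kept separate for the paired and the
    unpaired contrast (family size = number of features each).
    """
    features = list(pre.columns)
    if list(post.columns) != features or list(np_cohort.columns) != features:
        raise ValueError("feature columns must match across the three tables")
    if not pre.index.equals(post.index):
        post = post.reindex(pre.index)
        if post.isna().any().any():
            raise ValueError("pre and post must contain the same subjects")

    paired = [paired_compare(pre[f], post[f]) for f in features]
    unpaired = [unpaired_compare(np_cohort[f], post[f]) for f in features]
    p_adj_paired, sig_paired = bonferroni_adjust([c.p_raw for c in paired], alpha)
    p_adj_unpaired, sig_unpaired = bonferroni_adjust([c.p_raw for c in unpaired], alpha)

    rows = []
    for i, f in enumerate(features):
        rows.append(
            StatsRow(
                feature_id=f,
                pre_mean=float(pre[f].mean()),
                pre_sd=float(pre[f].std(ddof=1)),
                post_mean=float(post[f].mean()),
                post_sd=float(post[f].std(ddof=1)),
                np_mean=float(np_cohort[f].mean()),
                np_sd=float(np_cohort[f].std(ddof=1)),
                test_prepost=paired[i].test_name,
                p_prepost_raw=paired[i].p_raw,
                p_prepost_adj=float(p_adj_paired[i]),
                sig_prepost=bool(sig_paired[i]),
                test_nppost=unpaired[i].test_name,
                p_nppost_raw=unpaired[i].p_raw,
                p_nppost_adj=float(p_adj_unpaired[i]),
                sig_nppost=bool(sig_unpaired[i]),
            )
        )
    return rows


def rows_to_frame(rows: Sequence[StatsRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows]).set_index("feature_id")


def clinical_table(metadata_pre: pd.DataFrame, metadata_post: pd.DataFrame) -> pd.DataFrame:
    """Group summaries of the clinical metadata (knee score and subscales, BMI).

    Mirrors the published participant-characteristics layout at the level the
    generator models: one row per measure with pre/post/control mean (SD) and
    the two contrast p-values.
    """
    def derived(meta: pd.DataFrame) -> pd.DataFrame:
        items = meta[[f"oks_q{q}" for q in range(1, 13)]].to_numpy()
        vals = np.array([oks_subscales(r) for r in items])
        out = meta[["subject_id", "group"]].copy()
        out["oks_total"] = vals[:, 0]
        out["oks_pain_pct"] = vals[:, 1]
        out["oks_function_pct"] = vals[:, 2]
        out["bmi"] = meta["mass_kg"] / meta["height_m"] ** 2
        return out.set_index("subject_id")

    pre = derived(metadata_pre[metadata_pre["group"] == "OA"])
    ctrl = derived(metadata_pre[metadata_pre["group"] == "NP"])
    post = derived(metadata_post).reindex(pre.index)

    rows = []
    for measure in ["oks_total", "oks_pain_pct", "oks_function_pct", "bmi"]:
        pp = paired_compare(pre[measure], post[measure])
        up = unpaired_compare(ctrl[measure], post[measure])
        rows.append(
            {
                "measure": measure,
                "pre_mean": pre[measure].mean(),
                "pre_sd": pre[measure].std(ddof=1),
                "post_mean": post[measure].mean(),
                "post_sd": post[measure].std(ddof=1),
                "np_mean": ctrl[measure].mean(),
                "np_sd": ctrl[measure].std(ddof=1),
                "test_prepost": pp.test_name,
                "p_prepost": pp.p_raw,
                "test_nppost": up.test_name,
                "p_nppost": up.p_raw,
            }
        )
    return pd.DataFrame(rows).set_index("measure")
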