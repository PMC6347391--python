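"""Track biomechanical recovery after surgery on the belief simplex: project
the follow-up waveforms with the frozen PCA basis, classify them with the
frozen evidence model, and draw each patient's pre-to-post belief trajectory.

Nothing is refit on follow-up data.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

from common import FIGURES, RESULTS, SCRATCH, ensure_dirs
from gait_evidence.dst import ClassifierModel
from gait_evidence.pca_features import load_models
from gait_evidence.pipeline import _belief_table, classify_followup
from gait_evidence.plotting import recovery_arrows
from gait_evidence.waveform_io import WaveformSet


def main() -> None:
    ensure_dirs()
    model = ClassifierModel.from_json((SCRATCH / "classifier.json").read_text(encoding="utf-8"))
    pca = load_models(SCRATCH / "pca_models.json")
    post_waves = WaveformSet.from_csv(SCRATCH / "ensembles_post.csv")
    features_pre = pd.read_csv(
        RESULTS / "features_pre.csv", index_col="subject_id", float_precision="round_trip"
    )
    labels = pd.read_csv(SCRATCH / "metadata_pre.csv").set_index("subject_id")["group"]

    beliefs_pre = _belief_table(model, features_pre.loc[post_waves.subjects, model.features],
                                labels)
    beliefs_post = classify_followup(model, pca, post_waves,
                                     truth=labels.reindex(post_waves.subjects))
    beliefs_post.to_csv(RESULTS / "beliefs_post.csv")

    traj = pd.DataFrame(
        {
            "x_pre": beliefs_pre["x"], "y_pre": beliefs_pre["y"],
            "x_post": beliefs_post["x"], "y_post": beliefs_post["y"],
            "b_oa_pre": beliefs_pre["m_oa"], "b_oa_post": beliefs_post["m_oa"],
        }
    )
    traj["dx"] = traj["x_post"] - traj["x_pre"]
    traj.to_csv(RESULTS / "trajectories.csv", index_label="subject_id")
    recovery_arrows(beliefs_pre, beliefs_post, FIGURES / "simplex_recovery.svg")

    crossed = int(((traj["b_oa_pre"] > 0.5) & (beliefs_post["predicted"] == "NP")).sum())
    healthy_side = int((beliefs_post["predicted"] == "NP").sum())
    dominant = int((beliefs_post["m_oa"] > 0.5).sum())
    print(f"of {len(traj)} patients at follow-up: {healthy_side} classified on the healthy "
          f"side of the simplex, {dominant} remain in the dominant OA region (B(OA) > 0.5), "
          f"{crossed} crossed from dominant-OA to the healthy side")
    print(f"mean shift toward the healthy vertex: {-traj['dx'].mean():+.3f} simplex units")
    print(f"trajectories -> {RESULTS / 'trajectories.csv'}, "
          f"arrows -> {FIGURES / 'simplex_recovery.svg'}")


if __name__ == "__main__":
    main()
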