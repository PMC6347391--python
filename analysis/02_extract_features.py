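"""Extract PC-score features: fit per-channel PCA on the pre-operative
training set (patients + controls), apply the osteoarthritis-low sign
convention, and project both visits onto the frozen basis.

Finds how much waveform variance three components capture per channel and
writes the 69-column feature matrices for both visits.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs
from gait_evidence.pca_features import fit_pca, project, save_models
from gait_evidence.waveform_io import WaveformSet


def main() -> None:
    ensure_dirs()
    pre = WaveformSet.from_csv(SCRATCH / "ensembles_pre.csv")
    post = WaveformSet.from_csv(SCRATCH / "ensembles_post.csv")
    labels = pd.read_csv(SCRATCH / "metadata_pre.csv").set_index("subject_id")["group"]

    models, features_pre = fit_pca(pre, labels)
    features_post = project(models, post)
    save_models(models, SCRATCH / "pca_models.json")
    features_pre.to_csv(RESULTS / "features_pre.csv", index_label="subject_id")
    features_post.to_csv(RESULTS / "features_post.csv", index_label="subject_id")

    vf = pd.DataFrame(
        {
            "channel": [m.channel for m in models],
            "pc1_pct": [round(100 * m.variance_fraction[0], 1) for m in models],
            "pc2_pct": [round(100 * m.variance_fraction[1], 1) for m in models],
            "pc3_pct": [round(100 * m.variance_fraction[2], 1) for m in models],
            "n_sign_flips": [int(m.sign_flipped.sum()) for m in models],
        }
    ).set_index("channel")
    vf["top3_pct"] = (vf["pc1_pct"] + vf["pc2_pct"] + vf["pc3_pct"]).round(1)
    vf.to_csv(RESULTS / "variance_fractions.csv")

    print(f"fitted PCA on {features_pre.shape[0]} training subjects; "
          f"feature matrix has {features_pre.shape[1]} columns "
          f"({len(models)} channels x 3 PCs)")
    print(f"three components capture {vf['top3_pct'].min():.1f}-"
          f"{vf['top3_pct'].max():.1f}% of waveform variance per channel; "
          f"{int(vf['n_sign_flips'].sum())} of {3 * len(models)} columns were negated "
          "under the OA-low sign convention")
    print(f"feature matrices and variance table -> {RESULTS}")


if __name__ == "__main__":
    main()
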