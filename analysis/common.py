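"""Shared configuration for the numbered analysis scripts.

All scripts run from the repository root and chain through these locations:
bulky regenerable artifacts (waveform CSVs, fitted model JSON) live under
scratch/, summary tables and figures under results/analysis/.
"""

from pathlib import Path

SEED = 7

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results/analysis")
FIGURES = RESULTS / "figures"


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    FIGURES.mkdir(parents=True, exist_ok=True)
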