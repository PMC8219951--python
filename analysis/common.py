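"""Shared constants for the analysis drivers: cohort seeds and output paths."""
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

# study design: initial cohort of 9 animals, replication cohort of 4
EXP1 = {"label": "exp1", "n_animals": 9, "seed": 101}
EXP2 = {"label": "exp2", "n_animals": 4, "seed": 202}


def trace_dir(label: str) -> Path:
    return SCRATCH / "cohorts" / label


def kinematics_csv(label: str) -> Path:
    return RESULTS / f"kinematics_{label}.csv"
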