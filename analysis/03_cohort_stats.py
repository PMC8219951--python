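"""Tabulate reproducibility: mean ± SD, COV, and grade per metric x sensor.

Builds the summary table for both cohorts from the per-animal metrics of 02
and prints the human-readable rendering.  The machine stream should grade
"good" (COV < 5%) and the skull streams mostly "acceptable" (5-10%), with
time-to-peak the most variable metric.
"""
import pandas as pd

from common import EXP1, EXP2, RESULTS, kinematics_csv

from headkin import cohort_table
from headkin.repro_stats import render_table


def main() -> None:
    frames = [pd.read_csv(kinematics_csv(e["label"])) for e in (EXP1, EXP2)]
    df = pd.concat(frames, ignore_index=True)
    by = dict(zip(df["animal_id"], df["experiment"]))
    table = cohort_table(df, by)
    out = RESULTS / "cohort_table.csv"
    table.to_csv(out, index=False)
    print(render_table(table))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
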