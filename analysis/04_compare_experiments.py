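"""Machine-vs-skull transfer and cross-cohort replication statistics.

Within each cohort: paired t-tests of skull resultant vs machine metrics and
the headline percent transfer / percent duration change.  Across cohorts:
uncorrected one-vs-many t-tests of each replication animal against the
initial cohort (single-subject replication), and Pearson correlations
between machine and skull summaries pooled over all animals.
"""
import json

import pandas as pd

from common import EXP1, EXP2, RESULTS, kinematics_csv

from headkin.pipeline import compare_experiments


def main() -> None:
    exp1 = pd.read_csv(kinematics_csv(EXP1["label"]))
    exp2 = pd.read_csv(kinematics_csv(EXP2["label"]))
    result = compare_experiments(exp1, exp2)
    out = RESULTS / "comparisons.json"
    out.write_text(json.dumps(result, indent=2, sort_keys=True))

    for name in ("exp1", "exp2"):
        w = result["within"][name]
        t = w["peak_angular_velocity"]
        print(
            f"{name}: skull resultant peak = {w['peak_transfer_pct']:.1f}% of machine "
            f"(paired t{t['df']} = {t['t']:.2f}, p = {t['p']:.2g}); "
            f"FWHM {w['fwhm_change_pct']:+.1f}%"
        )
    for metric, block in result["one_vs_many"]["skull_resultant"].items():
        lo, hi = block["p_range"]
        print(f"one-vs-many ({metric}): p range {lo:.2f}-{hi:.2f}")
    for metric, c in result["correlations"].items():
        print(f"machine-skull r ({metric}): r = {c['r']:.2f}, p = {c['p']:.2f}, n = {c['n']}")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
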