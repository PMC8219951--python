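"""Condition each animal's traces and extract the three kinematic metrics.

Reads the trace files written by 01 (regenerating them deterministically if
scratch/ was cleaned), applies the CFC-1000 phaseless filter, computes the
triaxial resultant, spike-screens the skull streams, and extracts peak
angular velocity, FWHM, and 5%-rise time-to-peak per sensor stream.
Writes one row per animal x sensor to results/kinematics_<label>.csv.
"""
import pandas as pd

from common import EXP1, EXP2, RESULTS, kinematics_csv, trace_dir

from headkin import AngularRateTrace, CohortSpec, TriaxialTrace, simulate_cohort, summarize_animal
from headkin.repro_stats import summaries_to_frame


def load_or_simulate(exp) -> list:
    d = trace_dir(exp["label"])
    pairs = sorted(d.glob("*_machine.csv"))
    if pairs:
        out = []
        for mpath in pairs:
            animal = mpath.name.replace("_machine.csv", "")
            machine = AngularRateTrace.from_csv(mpath, "machine")
            skull = TriaxialTrace.from_csv(d / f"{animal}_skull.csv")
            out.append((animal, machine, skull))
        return out
    sim = simulate_cohort(
        CohortSpec(n_animals=exp["n_animals"], seed=exp["seed"]), label=exp["label"]
    )
    return [(a.animal_id, a.machine, a.skull) for a in sim.animals]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for exp in (EXP1, EXP2):
        rows = []
        for animal_id, machine, skull in load_or_simulate(exp):
            rows.extend(summarize_animal(machine, skull, animal_id=animal_id))
        df = summaries_to_frame(rows)
        df["experiment"] = exp["label"]
        df.to_csv(kinematics_csv(exp["label"]), index=False)
        res = df[df["sensor"] == "skull_resultant"]
        print(
            f"{exp['label']}: {res.shape[0]} animals; skull resultant peak "
            f"{res['peak_angular_velocity'].mean():.1f} rad/s, "
            f"FWHM {res['fwhm_ms'].mean():.2f} ms -> {kinematics_csv(exp['label']).name}"
        )


if __name__ == "__main__":
    main()
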