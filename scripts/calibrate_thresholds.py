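"""Calibrate the default classifier thresholds.

The decision rules are qualitative ("notable hydrophobic peak",
"lower electronic charge concentration"); this script makes them
numeric by generating the synthetic archetype distributions and
placing each threshold at the midpoint between the two relevant group
means:

* tau_hydrophobic_peak — between the mean beta1/beta2 max smoothed
  hydropathy of Group 1 and Group 3 archetypes;
* tau_charge           — between the mean loop max smoothed electronic
  charge concentration of Group 2 and Group 4;
* tau_hydrophilic      — between the mean loop hydrophilicity
  (negated mean smoothed hydropathy) of Group 2 and Group 4.

Run from the repository root:

    python scripts/calibrate_thresholds.py

and paste the printed YAML into src/phspec/data/classifier_config.yaml.
The shipped defaults were produced with the settings below.
"""

from __future__ import annotations

import numpy as np

from phspec.properties import compute_profile, load_scale
from phspec.synthetic import LOOP_WINDOW, generate_cases

N_PER_GROUP = 200
EFFECT = 1.0
SEED = 12345
WINDOW = 9


def main() -> None:
    scales = {s: load_scale(s) for s in ("H", "E")}
    lo, hi = LOOP_WINDOW
    stats: dict[int, dict[str, list[float]]] = {
        g: {"h_max": [], "e_max": [], "philic": []} for g in (1, 2, 3, 4)
    }
    for case in generate_cases(N_PER_GROUP, effect=EFFECT, seed=SEED):
        h = compute_profile(case.sequence, scales["H"], WINDOW).values
        e = compute_profile(case.sequence, scales["E"], WINDOW).values
        rec = stats[case.true_group]
        rec["h_max"].append(float(np.max(h[lo:hi])))
        rec["e_max"].append(float(np.max(e[lo:hi])))
        rec["philic"].append(float(-np.mean(h[lo:hi])))

    mean = {g: {k: float(np.mean(v)) for k, v in rec.items()}
            for g, rec in stats.items()}
    tau_peak = (mean[1]["h_max"] + mean[3]["h_max"]) / 2.0
    tau_charge = (mean[2]["e_max"] + mean[4]["e_max"]) / 2.0
    tau_philic = (mean[2]["philic"] + mean[4]["philic"]) / 2.0

    for g in (1, 2, 3, 4):
        print(f"# group {g}: h_max {mean[g]['h_max']:+.3f}  "
              f"e_max {mean[g]['e_max']:.3f}  philic {mean[g]['philic']:+.3f}")
    print("thresholds:")
    print(f"  tau_hydrophobic_peak: {tau_peak:.3f}")
    print(f"  tau_charge: {tau_charge:.3f}")
    print(f"  tau_hydrophilic: {tau_philic:.3f}")


if __name__ == "__main__":
    main()
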