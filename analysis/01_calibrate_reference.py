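#!/usr/bin/env python
"""Calibrate the reference virtual cyno to the synthetic multi-dose study.

Generates the emulated preclinical study (0.01/0.1/1 mg/kg weekly, n=4
per group, ADA-driven exposure loss in 4/4, 2/4, 1/4 animals), fits the
drug-potency parameters starting 1.7-fold off the generating values,
and reports the fit plus the first-dose IL6 peak timing per dose group
(the model places these peaks 2-6 h post dose).

Writes: results/reference_fit.json, results/il6_first_peak_times.csv
"""

import json
import time
from pathlib import Path

import pandas as pd

from tce_qsp.workflow import calibrate_reference_cyno, first_dose_il6_peak_times

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    t0 = time.time()
    fit, problem = calibrate_reference_cyno(seed=SEED, noise_cv=0.0)
    print(f"calibration finished in {time.time() - t0:.0f} s; loss {fit.loss:.3e}")
    for path, value in fit.free_values.items():
        print(f"  {path} = {value:.4g}")

    peak_times = first_dose_il6_peak_times(fit.subject, problem)
    table = pd.DataFrame(
        {"dose_mg_per_kg": list(peak_times), "il6_peak_time_h": list(peak_times.values())}
    )
    print("\nfirst-dose IL6 peak timing (calibrated subject):")
    print(table.to_string(index=False))

    (OUT / "reference_fit.json").write_text(
        json.dumps(
            {"loss": fit.loss, "free": fit.free_values,
             "per_observable_rms": fit.per_observable_rms,
             "fingerprint": fit.fingerprint(), "seed": SEED},
            indent=2,
        )
    )
    table.to_csv(OUT / "il6_first_peak_times.csv", index=False)


if __name__ == "__main__":
    main()
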