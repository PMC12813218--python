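"""Operating characteristics of the screen, at reduced simulation sizes.

Measures the family-wise type-I error under the null, the recovery power
across planted fold changes, and the flag rates on a pure abundance
confound with and without median normalization.  Pass a replicate count
to scale up (the acceptance script runs the full sizes).
"""

import sys
from pathlib import Path

import pandas as pd

from plf.operating import confound_rates, power_curve, type_i_error

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    reps = int(sys.argv[1]) if len(sys.argv) > 1 else 100
    rows = []
    t = type_i_error(n_reps=reps, base_seed=1)
    rows.append({"metric": "null_fwer", "value": t.fwer, "n": t.n_runs})
    for p in power_curve(n_reps=reps, base_seed=1):
        rows.append({"metric": f"power_fold_{p.fold_change}",
                     "value": p.power, "n": p.n_runs})
    c = confound_rates(n_reps=min(reps, 100), base_seed=1)
    rows.append({"metric": "confound_flag_rate_normalized",
                 "value": c.flag_rate_normalized, "n": c.n_runs})
    rows.append({"metric": "confound_flag_rate_unnormalized",
                 "value": c.flag_rate_unnormalized, "n": c.n_runs})
    df = pd.DataFrame(rows)
    ROOT.mkdir(exist_ok=True)
    df.to_csv(ROOT / "operating_characteristics.csv", index=False)
    print(df.to_string(index=False))
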