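"""FRAP kinetics across all conditions: normalize, fit, summarize.

Simulates 15 recovery traces per condition, applies the four-step
normalization, fits the two-phase exponential association model and
tabulates mean ± SEM of the mobile fraction, the diffusive share and the
time constants. Writes results/frap_condition_summaries.csv.
"""

from pathlib import Path

import pandas as pd

from cstquant import get_preset, list_presets
from cstquant.pipeline import recover_frap_condition

N_TRACES = 15


def main() -> None:
    frames = []
    for i, name in enumerate(sorted(n for n in list_presets() if n.startswith("CST-"))):
        summary, fits = recover_frap_condition(get_preset(name), seed=1 + i, n_traces=N_TRACES)
        frames.append(summary)
        vals = {r["parameter"]: r["mean"] for _, r in summary.iterrows()}
        print(
            f"{name:16s} Mob {100*vals['Mob_calc']:5.1f}%  A1 {100*vals['A1']:5.1f}%  "
            f"tau1 {vals['tau1']:4.2f} s  tau2 {vals['tau2']:5.2f} s  "
            f"({sum(f.converged for f in fits)}/{len(fits)} fits converged)"
        )
    Path("results").mkdir(exist_ok=True)
    pd.concat(frames).to_csv("results/frap_condition_summaries.csv", index=False)
    print("\nsummaries written to results/frap_condition_summaries.csv")


if __name__ == "__main__":
    main()
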