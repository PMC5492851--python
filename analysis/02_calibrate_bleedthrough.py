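"""Estimate donor/acceptor bleed-through from single-fluorophore scenes.

Pools pixels of 5 simulated reference scenes per seed and fits the
FRET-vs-reference-channel regression, for 10 seeds per mode; the slope is
the leak fraction (truth: A = 0.1 donor, B = 0.25 acceptor). Writes
results/bleedthrough_calibration.csv.
"""

from pathlib import Path

import pandas as pd

from cstquant import get_preset
from cstquant.pipeline import recover_bleedthrough

SEEDS = list(range(1, 11))


def main() -> None:
    preset = get_preset("paper-typical-bleedthrough")
    rows = []
    for kind, mode, truth in (("donor-only", "A", preset.bleed_A), ("acceptor-only", "B", preset.bleed_B)):
        mean_slope, fits = recover_bleedthrough(preset, SEEDS, kind=kind)
        for seed, fit in zip(SEEDS, fits):
            rows.append(
                {"parameter": mode, "seed": seed, "slope": fit.slope,
                 "intercept": fit.intercept, "r_squared": fit.r_squared,
                 "n_pixels": fit.n_pixels}
            )
        print(f"{mode}: mean slope {mean_slope:.4f} over {len(SEEDS)} seeds (truth {truth})")
    Path("results").mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv("results/bleedthrough_calibration.csv", index=False)
    print("per-seed fits written to results/bleedthrough_calibration.csv")


if __name__ == "__main__":
    main()
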