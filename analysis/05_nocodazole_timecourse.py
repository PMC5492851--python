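"""Real-time NFRET decay after microtubule depolymerization.

Simulates a nocodazole time course (on-filament NFRET excess halving every
600 s while the filament network thins), quantifies each frame with the
full pipeline, and reports the measured decay. Writes
results/nocodazole_timecourse.csv.
"""

from pathlib import Path

from cstquant import get_preset
from cstquant.calibration import BleedThroughParams
from cstquant.nfret import nfret_timecourse
from cstquant.pipeline import preprocess_image_set
from cstquant.simulate import generate_nocodazole_timecourse

TIMEPOINTS = [0.0, 300.0, 600.0, 900.0, 1200.0, 1800.0]


def main() -> None:
    preset = get_preset("CST-untreated")
    series = generate_nocodazole_timecourse(preset, seed=1, timepoints=TIMEPOINTS)
    processed = [(t, preprocess_image_set(images)) for t, images, _ in series]
    df = nfret_timecourse(processed, BleedThroughParams(preset.bleed_A, preset.bleed_B))
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/nocodazole_timecourse.csv", index=False)
    print(df.to_string(index=False))
    ratio = df["mean_nfret"].iloc[2] / df["mean_nfret"].iloc[0]
    print(f"\nNFRET at 10 min is {100*ratio:.0f}% of the initial value "
          "(microtubule disassembly releases the sensor)")


if __name__ == "__main__":
    main()
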