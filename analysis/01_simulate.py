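#!/usr/bin/env python
"""Generate the synthetic validation and survey dataset.

Emulates the full single-laboratory study design: nine steviol
glycosides in three food matrices (beverage, yogurt, snack), solvent and
matrix-matched calibration at 0.2-1.0 mg/L in triplicate, spikes at
0.2/0.5/1.0 mg/L in seven replicates, matrix-effect pairs, blanks, and
38 survey specimens (20 beverages, 10 yogurts, 8 snacks) in triplicate.
Writes the long-format observation table and the SRM peak list used by
all later steps.
"""

from pathlib import Path

from sweetval import GeneratorConfig, generate_peak_list, generate_validation_dataset
from sweetval.io import write_long_csv

SEED = 2023
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    config = GeneratorConfig(seed=SEED)
    df = generate_validation_dataset(config)
    peaks = generate_peak_list(config)
    OUT.mkdir(parents=True, exist_ok=True)
    write_long_csv(df, OUT / "observations.csv")
    peaks.to_csv(OUT / "peaks.csv", index=False)
    n_spike = (df["role"] == "spike").sum()
    n_sample = (df["role"] == "sample").sum()
    print(f"seed {SEED}: wrote {len(df)} observation rows "
          f"({n_spike} spike, {n_sample} survey) and {len(peaks)} peaks to {OUT}")


if __name__ == "__main__":
    main()
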