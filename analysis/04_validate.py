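#!/usr/bin/env python
"""Run the full method validation and write the report.

Per analyte and matrix: retention-time %RPD, matrix-matched linearity,
matrix effect per spike level, recovery / repeatability %RSD / HorRat
per level, LOD/LOQ in steviol equivalents, and pass/fail verdicts
against the acceptance bands.  Emits JSON (machine) and Markdown
(human) reports.
"""

from pathlib import Path

from sweetval import run_validation
from sweetval.io import read_long_csv, write_json

DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2023


def main() -> None:
    df = read_long_csv(DATA / "observations.csv")
    report = run_validation(df, seed=SEED)
    write_json(report.to_dict(), OUT / "validation.json")
    (OUT / "validation.md").write_text(report.to_markdown(), encoding="utf-8")

    n_fail = 0
    worst = []
    for analyte, matrices in report.results.items():
        for matrix, res in matrices.items():
            for crit, v in res["verdicts"].items():
                if v["evaluated"] and not v["pass"]:
                    n_fail += 1
                    worst.append(f"{analyte}/{matrix}/{crit}={v['value']:.4g}")
    verdict = "all criteria pass" if n_fail == 0 else \
        f"{n_fail} criterion cells out of band: {', '.join(worst)}"
    print(f"validated {len(report.results)} analytes x 3 matrices; {verdict}")
    print(f"reports -> {OUT / 'validation.json'}, {OUT / 'validation.md'}")


if __name__ == "__main__":
    main()
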