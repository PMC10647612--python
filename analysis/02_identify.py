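#!/usr/bin/env python
"""Assign SRM peaks to analytes and confirm identities.

Matches every peak against the built-in transition table (precursor ion,
quantifier and qualifier product ions, reference retention time within a
5% RPD window) and reports per-sample confirmation status, including the
isobaric pairs that retention time alone must separate.
"""

import csv
from collections import defaultdict
from pathlib import Path

from sweetval import assign_peaks, confirm_identity
from sweetval.io import read_peak_csv
from sweetval.srm import PeakObservation
from sweetval.transitions import DEFAULT_TRANSITIONS

DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = read_peak_csv(DATA / "peaks.csv")
    peaks = [PeakObservation(sample=r.sample, precursor_mz=r.precursor_mz,
                             product_mz=r.product_mz, rt=r.rt_min, area=r.area)
             for r in df.itertuples()]
    assignments = assign_peaks(peaks, DEFAULT_TRANSITIONS)
    recall = 100.0 * len(assignments) / len(peaks)

    by_key = defaultdict(list)
    for a in assignments:
        by_key[(a.peak.sample, a.analyte)].append(a)

    rows = []
    for (sample, analyte), group in sorted(by_key.items()):
        c = confirm_identity(group)
        rows.append({"sample": sample, "analyte": analyte,
                     "confirmed": c.confirmed, "n_qualifiers": c.n_qualifiers,
                     "quantifier_area": c.quantifier_area})

    out = OUT / "identification.csv"
    with open(out, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=rows[0].keys())
        writer.writeheader()
        writer.writerows(rows)

    n_confirmed = sum(r["confirmed"] for r in rows)
    print(f"assigned {len(assignments)}/{len(peaks)} peaks "
          f"(recall {recall:.1f}%); {n_confirmed}/{len(rows)} "
          f"analyte-sample identities confirmed -> {out}")


if __name__ == "__main__":
    main()
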