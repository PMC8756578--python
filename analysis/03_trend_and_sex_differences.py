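#!/usr/bin/env python
"""Validity checks on the estimated URLs: age trend and sex differences.

Serum creatinine rises with age as muscle mass accrues, so a valid URL
column must be monotone in age; external published tables built from
smaller strata show reversion points, which this script detects alongside
the estimated table's own columns. Also summarizes the adolescent
male−female URL gap. Reads results/reference_table.csv and the truth file;
writes results/trend_checks.csv.
"""

from pathlib import Path

import pandas as pd

from creatref import published
from creatref.reference_estimator import detect_reversions
from creatref.io_model import read_reference_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_reference_table(RESULTS / "reference_table.csv")

    rows = []
    for sex in ("M", "F"):
        sub = table[table["sex"] == sex]
        series = tuple(zip(sub["group"], sub["p97_5"]))
        report = detect_reversions(series, sex)
        rows.append({"series": f"estimated_{sex}", "n_bins": len(series),
                     "reversions": ";".join(report.reversion_ages)})
        state = "monotone" if report.is_monotone else f"reverts at {report.reversion_ages}"
        print(f"estimated URLs, sex {sex}: {state}")

    for name, series in published.EXTERNAL_URL_SERIES.items():
        report = detect_reversions(series, name[-1].upper())
        rows.append({"series": name, "n_bins": len(series),
                     "reversions": ";".join(report.reversion_ages)})
        print(f"{name}: reversion at {list(report.reversion_ages)}")

    adolescent = table[table["group"].isin(
        ["13–14 years", "14–15 years", "15–16 years", "16–17 years", "17–18 years"]
    )]
    pivot = adolescent.pivot(index="group", columns="sex", values="p97_5")
    diffs = (pivot["M"] - pivot["F"]).round(2)
    print(f"\nadolescent male−female URL differences (mg/dL):")
    for label, d in diffs.items():
        print(f"  {label}: {d:+.2f}")
    print(f"  range: {diffs.min():.2f} to {diffs.max():.2f}")
    rows.append({"series": "sex_difference_range", "n_bins": len(diffs),
                 "reversions": f"{diffs.min():.2f}..{diffs.max():.2f}"})

    pd.DataFrame(rows).to_csv(RESULTS / "trend_checks.csv", index=False)
    print(f"\nwrote {RESULTS / 'trend_checks.csv'}")


if __name__ == "__main__":
    main()
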