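#!/usr/bin/env python
"""Duration-truncation reliability of the directional ratio.

For every shorter cumulative window (60-240 s) versus the 300 s reference:
Bland-Altman bias and limits of agreement on relative differences, pairwise
coefficients of variation, and between-duration absolute-agreement ICCs,
plus within-duration mean-rating ICCs from the per-transition tables.
Writes reliability.csv per frequency and prints the duration trend.
"""

from pathlib import Path

import pandas as pd

from cpfr import reliability_battery, write_tables

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    for freq in (0.05, 0.10):
        tag = f"{freq:.2f}".replace(".", "")
        tdir = ROOT / "results" / "tables" / f"{tag}hz"
        summaries = pd.read_csv(tdir / "window_summaries.csv")
        transitions = pd.read_csv(
            ROOT / "scratch" / "tables" / f"{tag}hz" / "transitions.csv")
        report = reliability_battery(summaries, transitions,
                                     reference_window_s=300.0)
        write_tables({"reliability": report}, tdir)
        icc = report[(report.statistic == "icc_between_single")
                     & (report.metric == "ratio_abs")
                     & (report.direction == "INC")]
        cov = report[(report.statistic == "cov_mean_pct")
                     & (report.metric == "ratio_abs")
                     & (report.direction == "INC")]
        print(f"{freq} Hz INC, window vs 300 s reference:")
        for (_, i), (_, c) in zip(icc.iterrows(), cov.iterrows()):
            print(f"  {i.comparison:>11}: ICC={i.estimate:.3f} "
                  f"[{i.ci_low:.3f}-{i.ci_high:.3f}]  CoV={c.estimate:.1f}%")


if __name__ == "__main__":
    main()
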