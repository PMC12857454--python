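#!/usr/bin/env python
"""Group-level inference: direction x duration RM-ANOVA, Dunnett, Friedman.

Two-way fully repeated-measures ANOVA of the absolute and relative ratios
(factors: MAP direction, window duration) per frequency; Dunnett-style
Monte-Carlo-adjusted comparisons of each duration vs the 300 s reference;
and a Friedman rank test on a simulated end-tidal CO2 covariate table with
the small duration trend typical of progressive breathing drift.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from cpfr import dunnett_vs_reference, friedman_vs_reference, rm_anova_2way, write_tables
from cpfr.pipeline import direction_duration_table

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260926


def main() -> None:
    for freq in (0.05, 0.10):
        tag = f"{freq:.2f}".replace(".", "")
        tdir = ROOT / "tables" / f"{tag}hz"  # under results/
        summaries = pd.read_csv(tdir / "window_summaries.csv")
        anova_rows, comp_rows = [], []
        for metric in ("ratio_abs", "ratio_rel"):
            x, directions, durations = direction_duration_table(summaries, metric)
            results = rm_anova_2way(x)
            for r in results:
                anova_rows.append({"metric": metric, **dataclasses.asdict(r)})
            direction_p = results[0].p_value
            print(f"{freq} Hz {metric}: direction effect "
                  f"F({results[0].df1_corrected:.0f},"
                  f"{results[0].df2_corrected:.0f})={results[0].f_value:.2f}, "
                  f"p={direction_p:.4g}")
            for i, direction in enumerate(directions):
                for c in dunnett_vs_reference(
                        x[:, i, :], list(durations), 300.0, seed=SEED):
                    comp_rows.append({"metric": metric, "direction": direction,
                                      **dataclasses.asdict(c)})
        write_tables({"anova": pd.DataFrame(anova_rows),
                      "comparisons": pd.DataFrame(comp_rows)}, tdir)

    # simulated PET,CO2-like covariate: slight rise toward longer windows
    rng = np.random.default_rng(SEED)
    n, levels = 20, [60.0, 120.0, 180.0, 240.0, 300.0]
    base = rng.normal(40.0, 4.0, n)[:, None]
    trend = np.array([-0.5, -0.3, -0.2, -0.1, 0.0])
    covariate = base + trend + rng.normal(0, 0.4, (n, len(levels)))
    chi2, p, comps = friedman_vs_reference(covariate, levels, 300.0)
    print(f"covariate Friedman: chi2={chi2:.2f}, p={p:.4g}; "
          "adjusted p vs 300 s: "
          + ", ".join(f"{c.level:.0f}s={c.adjusted_p:.3g}" for c in comps))


if __name__ == "__main__":
    main()
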