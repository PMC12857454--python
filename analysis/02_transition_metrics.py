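#!/usr/bin/env python
"""Per-transition directional ratios and cumulative window summaries.

Reads the simulated beat series, detects the MAP/MCAv extremum trains,
computes the time-adjusted ratios for every INC and DEC transition, applies
the leading-instability and >3 SD artifact filters, and averages included
transitions over the 60/120/180/240/300 s cumulative windows.  The full
per-transition table (large, regenerable) goes under scratch/tables/; the
window summaries the later stages consume go under results/tables/.
"""

from pathlib import Path

from cpfr import load_config, read_beat_series, write_tables
from cpfr.pipeline import analyze_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    for freq in (0.05, 0.10):
        tag = f"{freq:.2f}".replace(".", "")
        cfg = load_config(None)
        cfg.protocol.frequency_hz = freq
        recordings = read_beat_series(
            ROOT / "scratch" / "synthetic" / f"beat_series_{tag}hz.csv")
        tables = analyze_cohort(recordings, cfg)
        write_tables({"transitions": tables["transitions"]},
                     ROOT / "scratch" / "tables" / f"{tag}hz")
        write_tables({"window_summaries": tables["window_summaries"]},
                     ROOT / "results" / "tables" / f"{tag}hz")
        trans = tables["transitions"]
        summ = tables["window_summaries"]
        kept = trans.included.mean()
        ref = summ[summ.window_s == 300.0].groupby(
            "direction")["mean_ratio_abs"].mean()
        print(f"{freq} Hz: {len(trans)} transitions ({kept:.0%} included); "
              f"300 s cohort mean ratio INC={ref['INC']:.3f} "
              f"DEC={ref['DEC']:.3f}")


if __name__ == "__main__":
    main()
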