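#!/usr/bin/env python
"""ICC-based sample-size planning for a reliability study.

Participants required to demonstrate that the intraclass correlation exceeds
a minimum acceptable level, for a grid of expected reliabilities and
repetition counts (two-sided alpha 0.05).
"""

from cpfr import SampleSizeParams, icc_sample_size


def main() -> None:
    headline = icc_sample_size(SampleSizeParams(
        rho0=0.80, rho1=0.90, alpha=0.05, power=0.95, k=3))
    print(f"rho0=0.80, rho1=0.90, alpha=0.05 (two-sided), power=0.95, k=3 "
          f"-> n = {headline}")
    print("\nsensitivity (power 0.95):")
    print("  rho1    k=2   k=3   k=5")
    for rho1 in (0.85, 0.90, 0.95):
        row = [icc_sample_size(SampleSizeParams(0.80, rho1, k=k, power=0.95))
               for k in (2, 3, 5)]
        print(f"  {rho1:.2f}  {row[0]:5d} {row[1]:5d} {row[2]:5d}")


if __name__ == "__main__":
    main()
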