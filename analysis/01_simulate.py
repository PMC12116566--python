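#!/usr/bin/env python
"""Generate the synthetic study quarter.

Draws a 30,000-report FAERS-like quarter from the default study
configuration (three aromatase inhibitors with brand spellings, the
recurrent dermatologic preferred terms under SOC 10040785, planted
drug-event associations, Weibull onset clocks, ~5% duplicate case
versions) and writes the five $-delimited tables plus the exact planted
truth to results/sim/.
"""

from pathlib import Path

from pvfaers.synthetic_data import default_ai_config, write_simulated_quarter

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
SEED = 20240101
N = 30_000


def main() -> None:
    cfg = default_ai_config(n_reports=N, seed=SEED)
    bundle, truth = write_simulated_quarter(cfg, OUT)
    print(f"wrote {len(bundle.demo)} demo rows ({N} base reports + duplicates) to {OUT}")
    print("planted pairs (expected 2x2 cells of the generating stream):")
    for key, t in truth.tables.items():
        print(
            f"  {key:32s} a={t['a']:7.1f} b={t['b']:8.1f} "
            f"c={t['c']:7.1f} d={t['d']:9.1f} odds-ratio={t['ror']}"
        )


if __name__ == "__main__":
    main()
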