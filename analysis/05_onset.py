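#!/usr/bin/env python
"""Time-to-onset analysis per drug-event pair.

Onset is days from therapy initiation (THER start of the matched drug) to
the event date; zero/negative intervals, erroneous dates (start after
event) and missing dates are excluded with reason codes.  Groups with
enough onsets get a maximum-likelihood Weibull fit whose shape CI
classifies the hazard (early-failure / random / late-failure).  Writes
results/tto.tsv and results/weibull.tsv.
"""

from pathlib import Path

import pandas as pd

import pvfaers as pv
from pvfaers.cohort import DrugLexicon, MeddraStub
from pvfaers.synthetic_data import DERM_SOC, default_ai_config
from pvfaers.tto import compute_tto, fit_weibull_by_pair, summarize_tto

ROOT = Path(__file__).resolve().parents[1] / "results"
DRUGS = ("anastrozole", "exemestane", "letrozole")


def main() -> None:
    bundle = pv.read_bundle(ROOT / "dedup")
    cfg = default_ai_config()
    lex, med = DrugLexicon.from_config(cfg), MeddraStub.from_config(cfg)
    derm = pv.filter_soc(bundle.reac, med, DERM_SOC)

    all_records, n_excl = [], {}
    for drug in DRUGS:
        ids = pv.match_drug(bundle.drug, lex, drug)
        cases = pv.build_cases(bundle, ids, derm, drug, lex, med, soc_code=DERM_SOC)
        records, excluded = compute_tto(cases)
        all_records.append(records)
        n_excl[drug] = excluded["reason"].value_counts().to_dict()
        print(f"{drug:12s} {len(records):4d} onset record(s); excluded {n_excl[drug]}")

    records = pd.concat(all_records, ignore_index=True)
    summary = summarize_tto(records, min_n=3)
    summary.to_csv(ROOT / "tto.tsv", sep="\t", index=False)
    fits = fit_weibull_by_pair(records, min_n=10)
    fits.to_csv(ROOT / "weibull.tsv", sep="\t", index=False)

    for _, row in summary.sort_values("median_days").head(3).iterrows():
        print(f"shortest onsets: {row['drug']}/{row['pt']} median {row['median_days']} d (n={row['n']})")
    for _, row in fits.iterrows():
        print(
            f"Weibull {row['drug']}/{row['pt']}: k={row['k']:.2f} "
            f"({row['k_lo']:.2f}-{row['k_hi']:.2f}), lambda={row['lambda']:.1f} d -> {row['class']}"
        )
    print("wrote results/tto.tsv and results/weibull.tsv")


if __name__ == "__main__":
    main()
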