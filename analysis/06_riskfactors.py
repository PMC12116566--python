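#!/usr/bin/env python
"""Risk-factor regression for dermatologic events.

Within each drug's deduplicated report universe, dermatologic-event
occurrence is regressed on hospitalization, age >= 65 and extreme body
weight (< 50 or > 100 kg) by maximum-likelihood logistic regression;
reports missing a covariate are excluded.  Writes results/risk_<drug>.tsv.
"""

from pathlib import Path

import pvfaers as pv
from pvfaers.cohort import DrugLexicon, MeddraStub
from pvfaers.riskfactors import build_design, fit_logistic, risk_table
from pvfaers.synthetic_data import DERM_SOC, default_ai_config

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = pv.read_bundle(ROOT / "dedup")
    cfg = default_ai_config()
    lex, med = DrugLexicon.from_config(cfg), MeddraStub.from_config(cfg)
    derm = pv.filter_soc(bundle.reac, med, DERM_SOC)

    for drug in ("anastrozole", "exemestane"):
        ids = pv.match_drug(bundle.drug, lex, drug)
        rows = build_design(bundle, ids, derm & ids)
        fit = fit_logistic(rows)
        table = risk_table(fit, rows)
        table.to_csv(ROOT / f"risk_{drug}.tsv", sep="\t", index=False)
        print(f"{drug}: n={fit.n} (excluded {rows.attrs['n_excluded']} incomplete)")
        for _, r in table.iterrows():
            print(
                f"  {r['covariate']:16s} OR {r['or']:.2f} "
                f"({r['ci_lo']:.2f}-{r['ci_hi']:.2f})  p={r['p']:.3f}"
            )


if __name__ == "__main__":
    main()
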