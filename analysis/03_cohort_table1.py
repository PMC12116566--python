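#!/usr/bin/env python
"""Extract dermatologic cases per drug and build the characteristics table.

For each aromatase inhibitor, reports are matched by generic/brand name
(suspect roles), restricted to preferred terms of the dermatologic SOC, and
summarised: counts and percentages by sex, weight band, age band, reporter
occupation, US/non-US and outcome code, plus medians.  Writes
results/table1.tsv (long form: block, label, stratum, n, pct).
"""

from pathlib import Path

import pandas as pd

import pvfaers as pv
from pvfaers.cohort import DrugLexicon, MeddraStub, characteristics
from pvfaers.synthetic_data import DERM_SOC, default_ai_config

ROOT = Path(__file__).resolve().parents[1] / "results"
DRUGS = ("anastrozole", "exemestane", "letrozole")


def main() -> None:
    bundle = pv.read_bundle(ROOT / "dedup")
    cfg = default_ai_config()
    lex, med = DrugLexicon.from_config(cfg), MeddraStub.from_config(cfg)
    derm = pv.filter_soc(bundle.reac, med, DERM_SOC)

    per_drug = {}
    for drug in DRUGS:
        ids = pv.match_drug(bundle.drug, lex, drug)
        per_drug[drug] = pv.build_cases(
            bundle, ids, derm, drug, lex, med, soc_code=DERM_SOC
        )
        print(f"{drug:12s} {len(per_drug[drug]):5d} dermatologic case(s)")

    cases = pd.concat(per_drug.values(), ignore_index=True)
    table = characteristics(cases, strata=per_drug)
    table.to_csv(ROOT / "table1.tsv", sep="\t", index=False)

    sex = table[(table["block"] == "sex") & (table["stratum"] == "all")]
    female = sex[sex["label"] == "Female"].iloc[0]
    print(
        f"all drugs: {len(cases)} cases; female {int(female['n'])} "
        f"({female['pct']}%) — table written to results/table1.tsv"
    )


if __name__ == "__main__":
    main()
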