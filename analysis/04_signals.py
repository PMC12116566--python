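#!/usr/bin/env python
"""Disproportionality analysis: drug-level and PT-level scans.

For each aromatase inhibitor, the 2x2 table against the deduplicated report
universe yields ROR (Wald 95% CI), PRR (chi-square), BCPNN IC (IC025) and
MGPS EBGM (EBGM05); a pair is a positive signal when the lower ROR bound
exceeds 1 with at least 3 reports.  Writes the per-drug summary
(results/signals_drug.tsv, the forest-plot input) and the per-PT scans
(results/signals_pt.tsv).
"""

from pathlib import Path

import pandas as pd

import pvfaers as pv
from pvfaers.cohort import DrugLexicon, MeddraStub
from pvfaers.signals import pt_scan, results_to_frame, soc_signal
from pvfaers.synthetic_data import DERM_SOC, default_ai_config

ROOT = Path(__file__).resolve().parents[1] / "results"
DRUGS = ("anastrozole", "exemestane", "letrozole")


def main() -> None:
    bundle = pv.read_bundle(ROOT / "dedup")
    cfg = default_ai_config()
    lex, med = DrugLexicon.from_config(cfg), MeddraStub.from_config(cfg)

    drug_rows, pt_rows = [], []
    for drug in DRUGS:
        ids = pv.match_drug(bundle.drug, lex, drug)
        r = soc_signal(bundle, ids, med, DERM_SOC, drug=drug)
        drug_rows.append(r)
        print(
            f"{drug:12s} a={r.a:5d}  ROR {r.ror:.2f} ({r.ror_lo:.2f}-{r.ror_hi:.2f})  "
            f"PRR {r.prr:.2f} (chi2 {r.chi2:.1f})  EBGM {r.ebgm:.2f} ({r.ebgm05:.2f})  "
            f"IC {r.ic:.2f} ({r.ic025:.2f})  signal={r.is_signal}"
        )
        scan = pt_scan(bundle, ids, med, DERM_SOC, drug=drug)
        pt_rows.extend(scan)
        pos = [s for s in scan if s.is_signal]
        print(f"             {len(pos)} positive PT signal(s) of {len(scan)} scanned; "
              f"top: {scan[0].event} (ROR {scan[0].ror:.2f})")

    results_to_frame(drug_rows).to_csv(ROOT / "signals_drug.tsv", sep="\t", index=False)
    results_to_frame(pt_rows).to_csv(ROOT / "signals_pt.tsv", sep="\t", index=False)
    print("wrote results/signals_drug.tsv and results/signals_pt.tsv")


if __name__ == "__main__":
    main()
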