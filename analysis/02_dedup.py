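#!/usr/bin/env python
"""Deduplicate case versions.

Within each CASEID only the report version with the most recent FDA_DT is
retained (ties broken by the highest PRIMARYID); all five tables are then
restricted to the kept reports.  Writes the deduplicated bundle to
results/dedup/ and the dropped primaryids to results/dedup_audit.tsv.
"""

from pathlib import Path

import pandas as pd

import pvfaers as pv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = pv.read_bundle(ROOT / "sim")
    kept, dropped = pv.deduplicate(bundle.demo)
    ded = pv.restrict_bundle(bundle, set(kept["primaryid"].astype(int)))
    pv.write_bundle(ded, ROOT / "dedup")
    pd.DataFrame({"dropped_primaryid": sorted(dropped)}).to_csv(
        ROOT / "dedup_audit.tsv", sep="\t", index=False
    )
    print(
        f"kept {len(kept)} of {len(bundle.demo)} report versions "
        f"({len(dropped)} duplicates dropped, "
        f"{100 * len(dropped) / len(bundle.demo):.2f}%)"
    )


if __name__ == "__main__":
    main()
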