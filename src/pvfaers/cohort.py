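"""Cohort extraction and descriptive characteristics.

Target-drug reports are found by exact matching of normalised drug name
strings (generic and brand spellings); event restriction goes through a
MedDRA-like preferred-term -> system-organ-class stub dictionary.  The
descriptive table mirrors the usual pharmacovigilance case-series summary:
counts and percentages by sex, weight band, age band, reporter occupation,
US/non-US origin and outcome code, plus medians with min-max for age and
weight, stratified by drug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from .faers_io import QuarterBundle

logger = logging.getLogger(__name__)

LBS_TO_KG = 0.453592
DEFAULT_ROLES = frozenset({"PS", "SS"})


def normalize_name(s: str) -> str:
    """Lowercase, trim whitespace and strip trailing punctuation."""
    return str(s).strip().rstrip(".,;:!").strip().lower()


@dataclass
class DrugLexicon:
    """Accepted spellings per generic drug name (case-insensitive)."""

    aliases: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.aliases = {
            normalize_name(g): {normalize_name(a) for a in al} | {normalize_name(g)}
            for g, al in self.aliases.items()
        }

    def names_for(self, generic: str) -> set[str]:
        key = normalize_name(generic)
        if key not in self.aliases:
            raise KeyError(f"unknown target drug {generic!r}")
        return self.aliases[key]

    @classmethod
    def from_file(cls, path: str | Path) -> "DrugLexicon":
        """Two-column text: ``generic<TAB>alias``, one alias per line."""
        aliases: dict[str, set[str]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            generic, alias = line.split("\t", 1)
            aliases.setdefault(generic, set()).add(alias)
        return cls(aliases)

    @classmethod
    def from_config(cls, config) -> "DrugLexicon":
        """Build from a :class:`~pvfaers.synthetic_data.SimulationConfig`."""
        return cls({d.generic: set(d.brands) for d in config.drugs})

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{g}\t{a}" for g in sorted(self.aliases) for a in sorted(self.aliases[g])
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class MeddraStub:
    """Preferred term -> (SOC code, SOC name), one SOC per PT.

    A stand-in for the licensed MedDRA hierarchy sufficient for SOC-level
    restriction of the synthetic stream.
    """

    mapping: dict[str, tuple[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {normalize_name(pt): (int(c), n) for pt, (c, n) in self.mapping.items()}

    def soc_of(self, pt: str) -> tuple[int, str] | None:
        return self.mapping.get(normalize_name(pt))

    def pts_in_soc(self, soc_code: int) -> set[str]:
        return {pt for pt, (c, _) in self.mapping.items() if c == soc_code}

    def soc_codes(self) -> set[int]:
        return {c for c, _ in self.mapping.values()}

    @classmethod
    def from_file(cls, path: str | Path) -> "MeddraStub":
        """Two-column text: ``PT<TAB>SOC code``; optional third column SOC name."""
        mapping: dict[str, tuple[int, str]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            mapping[parts[0]] = (int(parts[1]), parts[2] if len(parts) > 2 else "")
        return cls(mapping)

    @classmethod
    def from_config(cls, config) -> "MeddraStub":
        return cls({t.name: (t.soc_code, t.soc_name) for t in config.pts})

    def to_file(self, path: str | Path) -> None:
        lines = [f"{pt}\t{c}\t{n}" for pt, (c, n) in sorted(self.mapping.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def match_drug(
    drug: pd.DataFrame,
    lexicon: DrugLexicon,
    target: str,
    roles: frozenset[str] | set[str] = DEFAULT_ROLES,
) -> set[int]:
    """Primaryids whose DRUG rows name ``target`` (any accepted spelling of
    the generic or a brand, matched exactly after normalisation) in one of
    the given roles."""
    names = lexicon.names_for(target)
    role_ok = drug["role_cod"].isin(list(roles))
    by_name = drug["drugname"].map(normalize_name, na_action="ignore").isin(names)
    by_ai = drug["prod_ai"].map(normalize_name, na_action="ignore").isin(names)
    hit = role_ok & (by_name.fillna(False) | by_ai.fillna(False))
    return set(drug.loc[hit, "primaryid"].astype(int))


def filter_soc(reac: pd.DataFrame, meddra: MeddraStub, soc_code: int) -> set[int]:
    """Primaryids having at least one PT mapped to ``soc_code``.

    PTs absent from the dictionary are logged and ignored.
    """
    if soc_code not in meddra.soc_codes():
        raise ValueError(f"SOC code {soc_code} not present in the dictionary")
    norm = reac["pt"].map(normalize_name, na_action="ignore")
    unknown = sorted(set(norm.dropna()) - set(meddra.mapping))
    if unknown:
        logger.warning("ignoring %d PT(s) absent from the dictionary: %s",
                       len(unknown), unknown[:5])
    wanted = meddra.pts_in_soc(soc_code)
    hit = norm.isin(wanted)
    return set(reac.loc[hit.fillna(False), "primaryid"].astype(int))


def convert_age_years(age: float | None, age_cod: str | None) -> float | None:
    """Age in years from FAERS value + unit code; unknown unit -> missing."""
    if age is None or pd.isna(age):
        return None
    unit = (age_cod or "YR") if not pd.isna(age_cod) else "YR"
    unit = str(unit).upper()
    if unit == "YR":
        return float(age)
    if unit == "MON":
        return float(age) / 12.0
    if unit == "DY":
        return float(age) / 365.25
    return None


def convert_weight_kg(wt: float | None, wt_cod: str | None) -> float | None:
    """Weight in kg from FAERS value + unit code; unknown unit -> missing."""
    if wt is None or pd.isna(wt):
        return None
    unit = (wt_cod or "KG") if not pd.isna(wt_cod) else "KG"
    unit = str(unit).upper()
    if unit == "KG":
        return float(wt)
    if unit == "LBS":
        return float(wt) * LBS_TO_KG
    return None


def build_cases(
    bundle: QuarterBundle,
    matched: set[int],
    derm: set[int],
    target: str,
    lexicon: DrugLexicon,
    meddra: MeddraStub,
    soc_code: int | None = None,
) -> pd.DataFrame:
    """One case row per primaryid in ``matched & derm``.

    Units are converted (age to years, weight to kg); ``pts`` holds the
    report's PTs within ``soc_code`` (all PTs when None);
    ``therapy_start_dt`` is the earliest valid THER start date among rows
    linked to a DRUG row naming the target.
    """
    ids = matched & derm
    demo = bundle.demo[bundle.demo["primaryid"].isin(list(ids))].copy()

    age_years = [
        convert_age_years(a, c) for a, c in zip(demo["age"], demo["age_cod"])
    ]
    weight_kg = [
        convert_weight_kg(w, c) for w, c in zip(demo["wt"], demo["wt_cod"])
    ]

    # PTs per report, restricted to the SOC when requested
    reac = bundle.reac[bundle.reac["primaryid"].isin(list(ids))]
    if soc_code is not None:
        wanted = meddra.pts_in_soc(soc_code)
        norm = reac["pt"].map(normalize_name, na_action="ignore")
        reac = reac[norm.isin(wanted).fillna(False)]
    pts_by_id = reac.groupby("primaryid")["pt"].agg(lambda s: frozenset(s.dropna()))

    outc = bundle.outc[bundle.outc["primaryid"].isin(list(ids))]
    outc_by_id = outc.groupby("primaryid")["outc_cod"].agg(lambda s: frozenset(s.dropna()))

    # therapy start of the matched drug: link THER.dsg_drug_seq to the DRUG
    # rows that name the target, take the earliest valid date
    names = lexicon.names_for(target)
    drug = bundle.drug[bundle.drug["primaryid"].isin(list(ids))]
    is_target = (
        drug["drugname"].map(normalize_name, na_action="ignore").isin(names).fillna(False)
        | drug["prod_ai"].map(normalize_name, na_action="ignore").isin(names).fillna(False)
    )
    target_rows = drug.loc[is_target, ["primaryid", "drug_seq"]]
    ther = bundle.ther.merge(
        target_rows,
        left_on=["primaryid", "dsg_drug_seq"],
        right_on=["primaryid", "drug_seq"],
    )
    start_by_id = ther.dropna(subset=["start_dt"]).groupby("primaryid")["start_dt"].min()

    pid = demo["primaryid"].astype(int)
    cases = pd.DataFrame(
        {
            "primaryid": pid.to_numpy(),
            "drug": target,
            "pts": pid.map(lambda p: pts_by_id.get(p, frozenset())).to_numpy(),
            "sex": demo["sex"].fillna("UNK").to_numpy(),
            "age_years": pd.array(
                [pd.NA if v is None else v for v in age_years], dtype="Float64"
            ),
            "weight_kg": pd.array(
                [pd.NA if v is None else v for v in weight_kg], dtype="Float64"
            ),
            "occp_cod": demo["occp_cod"].to_numpy(),
            "reporter_country": demo["reporter_country"].to_numpy(),
            "outcomes": pid.map(lambda p: outc_by_id.get(p, frozenset())).to_numpy(),
            "event_dt": demo["event_dt"].to_numpy(),
            "therapy_start_dt": pd.array(pid.map(start_by_id).to_numpy(), dtype="Int64"),
        }
    )
    return cases.sort_values("primaryid").reset_index(drop=True)


def percentage(count: int, total: int) -> float:
    """Percentage on the stratum total, rounded half-up to 2 decimals."""
    if total == 0:
        return 0.0
    pct = Decimal(count) * Decimal(100) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# banding chosen so the printed labels partition without overlap
WEIGHT_BANDS = (
    ("<80", lambda w: w < 80),
    ("80-100", lambda w: (w >= 80) & (w <= 100)),
    (">100", lambda w: w > 100),
)
AGE_BANDS = (
    ("<18", lambda a: a < 18),
    ("18-44", lambda a: (a >= 18) & (a < 45)),
    ("45-65", lambda a: (a >= 45) & (a <= 65)),
    (">65", lambda a: a > 65),
)
OCCP_LABELS = (("CN", "Consumer"), ("MD", "Physician"), ("PH", "Pharmacist"),
               ("OT", "Other health-professional"))
OUTCOME_LABELS = (("DE", "Death"), ("DS", "Disability"), ("HO", "Hospitalization"),
                  ("LT", "Life-threatening"), ("OT", "Other serious"),
                  ("RI", "Required intervention"))


def _block_rows(block: str, labels_counts: list[tuple[str, int]], total: int, stratum: str):
    return [
        {"block": block, "label": lab, "stratum": stratum, "n": cnt,
         "pct": percentage(cnt, total)}
        for lab, cnt in labels_counts
    ]


def _stratum_summary(cases: pd.DataFrame, stratum: str) -> list[dict]:
    total = len(cases)
    rows: list[dict] = [
        {"block": "total", "label": "reports", "stratum": stratum, "n": total,
         "pct": percentage(total, total) if total else 0.0}
    ]

    sex = cases["sex"].fillna("UNK")
    rows += _block_rows(
        "sex",
        [("Female", int((sex == "F").sum())), ("Male", int((sex == "M").sum())),
         ("Unknown", int((~sex.isin(["F", "M"])).sum()))],
        total, stratum,
    )

    wt = pd.to_numeric(cases["weight_kg"], errors="coerce")
    counts = [(lab, int(fn(wt).fillna(False).sum())) for lab, fn in WEIGHT_BANDS]
    counts.append(("Unknown", int(wt.isna().sum())))
    rows += _block_rows("weight_kg", counts, total, stratum)

    age = pd.to_numeric(cases["age_years"], errors="coerce")
    counts = [(lab, int(fn(age).fillna(False).sum())) for lab, fn in AGE_BANDS]
    counts.append(("Unknown", int(age.isna().sum())))
    rows += _block_rows("age_years", counts, total, stratum)

    occ = cases["occp_cod"]
    counts = [(name, int((occ == code).sum())) for code, name in OCCP_LABELS]
    counts.append(("Unknown", int((~occ.isin([c for c, _ in OCCP_LABELS])).sum())))
    rows += _block_rows("occupation", counts, total, stratum)

    country = cases["reporter_country"]
    rows += _block_rows(
        "country",
        [("US", int((country == "US").sum())),
         ("Non-US", int((country.notna() & (country != "US")).sum())),
         ("Unknown", int(country.isna().sum()))],
        total, stratum,
    )

    outcomes = cases["outcomes"]
    counts = [
        (name, int(outcomes.map(lambda s, c=code: c in s).sum()))
        for code, name in OUTCOME_LABELS
    ]
    counts.append(("Unknown", int(outcomes.map(len).eq(0).sum())))
    # outcome rows do not partition (a report can carry several codes); the
    # Unknown row counts reports with none
    rows += [
        {"block": "outcomes", "label": lab, "stratum": stratum, "n": cnt,
         "pct": percentage(cnt, total)}
        for lab, cnt in counts
    ]

    for name, series in (("age_years", age), ("weight_kg", wt)):
        vals = series.dropna().astype(float)
        rows.append(
            {
                "block": f"median_{name}",
                "label": "median (min-max)",
                "stratum": stratum,
                "n": len(vals),
                "median": float(np.median(vals)) if len(vals) else float("nan"),
                "min": float(vals.min()) if len(vals) else float("nan"),
                "max": float(vals.max()) if len(vals) else float("nan"),
            }
        )
    return rows


def characteristics(
    cases: pd.DataFrame, strata: dict[str, pd.DataFrame] | None = None
) -> pd.DataFrame:
    """Descriptive characteristics table (long form).

    ``strata`` maps stratum name -> case subset; an ``all`` stratum over the
    full input is always included.  Percentages are computed on the stratum
    total and rounded half-up to 2 decimals.
    """
    if cases.empty and not strata:
        raise ValueError("characteristics requires at least one case")
    rows = _stratum_summary(cases, "all")
    for name, sub in (strata or {}).items():
        rows += _stratum_summary(sub, name)
    return pd.DataFrame(rows)
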