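"""Synthetic FAERS-like spontaneous-report streams with known ground truth.

The generator emits a :class:`~pvfaers.faers_io.QuarterBundle` whose joint
drug x event structure is controlled: for each *planted* drug-event pair the
2x2 contingency table of the generating process has a prescribed odds ratio,
solved in closed form from the two marginals (the Plackett construction for
a 2x2 with given margins and cross-product ratio).  The returned
:class:`PlantedTruth` therefore carries the *exact* expected table for every
planted pair, not a Monte-Carlo approximation.

Realism knobs emulate the failure modes of real spontaneous-report data:
duplicate case versions (same CASEID, new PRIMARYID, later FDA_DT),
erroneous therapy dates (start after event), partial/missing dates and
demographics, generic-vs-brand drug spellings in random letter case, and
Weibull-distributed onset clocks for selected pairs so that event dates are
consistent with therapy start dates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .faers_io import QuarterBundle, write_bundle

OUTCOME_CODES = ("DE", "DS", "HO", "LT", "OT", "RI")

#: System organ class code for dermatologic disorders used throughout.
DERM_SOC = 10040785


@dataclass(frozen=True)
class DrugSpec:
    """One drug in the simulated market: generic name, brand names, and the
    marginal probability that a report mentions it.  ``suspect`` drugs are
    written with role PS (primary suspect); others are co-medications (C)."""

    generic: str
    brands: tuple[str, ...]
    p: float
    suspect: bool = False


@dataclass(frozen=True)
class PtSpec:
    """One MedDRA-like preferred term with its SOC mapping and marginal
    reporting probability."""

    name: str
    soc_code: int
    soc_name: str
    p: float


@dataclass(frozen=True)
class PlantedSignal:
    """A drug-event pair whose generating 2x2 table has odds ratio
    ``ror_multiplier`` (1 = independence)."""

    drug: str
    pt: str
    ror_multiplier: float


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic quarter.

    Probabilities are per base report (before duplication).  ``onset_models``
    maps (generic, pt) to a Weibull (shape k, scale lam-days) onset clock;
    reports carrying that pair get event_dt = therapy start + onset.
    """

    n_reports: int = 20_000
    seed: int = 0
    drugs: list[DrugSpec] = field(default_factory=list)
    pts: list[PtSpec] = field(default_factory=list)
    planted_signals: list[PlantedSignal] = field(default_factory=list)
    duplicate_rate: float = 0.05
    bad_date_rate: float = 0.02
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.33,
            "wt": 0.31,
            "event_dt": 0.15,
            "start_dt": 0.15,
            "occp_cod": 0.09,
            "reporter_country": 0.025,
            "prod_ai": 0.30,
        }
    )
    sex_mix: dict[str, float] = field(
        default_factory=lambda: {"F": 0.967, "M": 0.008, "UNK": 0.025}
    )
    age_mean: float = 66.0
    age_sd: float = 11.0
    age_young_frac: float = 0.015  # small paediatric admixture, uniform 2-17 y
    age_unit_fracs: dict[str, float] = field(
        default_factory=lambda: {"YR": 0.96, "MON": 0.025, "DY": 0.015}
    )
    wt_mean: float = 68.0
    wt_sd: float = 14.0
    wt_lbs_frac: float = 0.15
    onset_models: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: {
            "DE": 0.052,
            "DS": 0.034,
            "HO": 0.225,
            "LT": 0.030,
            "OT": 0.493,
            "RI": 0.005,
        }
    )
    occp_mix: dict[str, float] = field(
        default_factory=lambda: {"MD": 0.44, "CN": 0.23, "OT": 0.18, "PH": 0.06, "UNK": 0.09}
    )
    us_frac: float = 0.27
    quarter_label: str = "2024Q1"

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not self.drugs or not self.pts:
            raise ValueError("drug and PT catalogs must be non-empty")
        for rate_name in ("duplicate_rate", "bad_date_rate"):
            v = getattr(self, rate_name)
            if not 0 <= v < 1:
                raise ValueError(f"{rate_name} must be in [0, 1)")
        for d in self.drugs:
            if not 0 < d.p < 1:
                raise ValueError(f"marginal probability out of (0,1) for drug {d.generic}")
        for t in self.pts:
            if not 0 < t.p < 1:
                raise ValueError(f"marginal probability out of (0,1) for PT {t.name}")
        drug_names = {d.generic for d in self.drugs}
        pt_names = {t.name for t in self.pts}
        seen_pts: set[str] = set()
        for sig in self.planted_signals:
            if sig.drug not in drug_names:
                raise ValueError(f"planted signal references unknown drug {sig.drug!r}")
            if sig.pt not in pt_names:
                raise ValueError(f"planted signal references unknown PT {sig.pt!r}")
            if sig.ror_multiplier <= 0:
                raise ValueError(f"ror_multiplier must be > 0 for ({sig.drug}, {sig.pt})")
            if sig.pt in seen_pts:
                raise ValueError(
                    f"PT {sig.pt!r} appears in more than one planted signal; "
                    "each PT may be planted against at most one drug"
                )
            seen_pts.add(sig.pt)
        for (k, lam) in self.onset_models.values():
            if k <= 0 or lam <= 0:
                raise ValueError("Weibull onset parameters must be positive")

    def drug_spec(self, generic: str) -> DrugSpec:
        for d in self.drugs:
            if d.generic == generic:
                return d
        raise KeyError(generic)

    def pt_spec(self, name: str) -> PtSpec:
        for t in self.pts:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class PlantedTruth:
    """Exact expected structure of the pre-duplication report stream.

    ``tables`` maps "drug|pt" to the expected 2x2 cells (a, b, c, d) of the
    generating process (summing to n_reports) and the planted odds ratio;
    ``onsets`` maps the same key to the (shape, scale) of the onset clock.
    """

    n_reports: int
    tables: dict[str, dict[str, float]]
    onsets: dict[str, dict[str, float]]

    @staticmethod
    def key(drug: str, pt: str) -> str:
        return f"{drug}|{pt}"

    def expected_table(self, drug: str, pt: str) -> tuple[float, float, float, float]:
        t = self.tables[self.key(drug, pt)]
        return t["a"], t["b"], t["c"], t["d"]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


class GenerationError(ValueError):
    """Raised when a planted configuration is infeasible."""


def joint_cell_probability(p_drug: float, p_pt: float, odds_ratio: float) -> float:
    """P(drug present AND pt present) for a 2x2 with the given margins and
    odds ratio (Plackett closed form).

    For ``odds_ratio == 1`` this is the independence product.  Raises
    :class:`GenerationError` when the implied cell leaves [0, min(margins)].
    """
    m = odds_ratio
    if m == 1.0:
        p11 = p_drug * p_pt
    else:
        s = 1.0 + (p_drug + p_pt) * (m - 1.0)
        disc = s * s - 4.0 * m * (m - 1.0) * p_drug * p_pt
        if disc < 0:
            raise GenerationError(
                f"odds ratio {m} infeasible for margins ({p_drug}, {p_pt})"
            )
        p11 = (s - math.sqrt(disc)) / (2.0 * (m - 1.0))
    eps = 1e-12
    if not (-eps <= p11 <= min(p_drug, p_pt) + eps):
        raise GenerationError(
            f"odds ratio {m} pushes joint cell past its margin for ({p_drug}, {p_pt})"
        )
    return min(max(p11, 0.0), min(p_drug, p_pt))


def expected_cells(
    n: int, p_drug: float, p_pt: float, odds_ratio: float
) -> tuple[float, float, float, float]:
    """Expected (a, b, c, d) of the generating 2x2 table at size ``n``."""
    p11 = joint_cell_probability(p_drug, p_pt, odds_ratio)
    a = n * p11
    b = n * (p_drug - p11)
    c = n * (p_pt - p11)
    d = n - a - b - c
    return a, b, c, d


# ---------------------------------------------------------------------------
# default study configuration: three aromatase inhibitors on a breast-cancer
# reporting background
# ---------------------------------------------------------------------------

#: The recurrent dermatologic preferred terms of the study, all mapped to the
#: dermatologic SOC.
DERM_PTS = (
    ("Alopecia", 0.012),
    ("Nail disorder", 0.004),
    ("Onychoclasis", 0.003),
    ("Night sweats", 0.006),
    ("Urticaria", 0.007),
    ("Rash", 0.020),
    ("Pruritus", 0.014),
    ("Dry skin", 0.006),
    ("Erythema", 0.009),
    ("Hyperhidrosis", 0.008),
    ("Skin ulcer", 0.003),
    ("Bullous dermatitis", 0.002),
    ("Rash maculo-papular", 0.004),
    ("Angioedema", 0.004),
    ("Rash pruritic", 0.004),
    ("Abnormal hair growth", 0.002),
    ("Anhidrosis", 0.001),
    ("Pseudo cellulitis", 0.001),
    ("Nail toxicity", 0.001),
)

_BACKGROUND_PTS = (
    ("Nausea", 10017947, "Gastrointestinal disorders", 0.09),
    ("Diarrhoea", 10017947, "Gastrointestinal disorders", 0.06),
    ("Vomiting", 10017947, "Gastrointestinal disorders", 0.05),
    ("Headache", 10029205, "Nervous system disorders", 0.07),
    ("Dizziness", 10029205, "Nervous system disorders", 0.05),
    ("Arthralgia", 10028395, "Musculoskeletal disorders", 0.08),
    ("Myalgia", 10028395, "Musculoskeletal disorders", 0.04),
    ("Fatigue", 10018065, "General disorders", 0.12),
    ("Hot flush", 10047065, "Vascular disorders", 0.06),
    ("Osteoporosis", 10028395, "Musculoskeletal disorders", 0.03),
    ("Dyspnoea", 10038738, "Respiratory disorders", 0.05),
    ("Insomnia", 10037175, "Psychiatric disorders", 0.04),
)

_BACKGROUND_DRUGS = (
    DrugSpec("tamoxifen", ("Nolvadex", "Soltamox"), 0.09),
    DrugSpec("metformin", ("Glucophage",), 0.10),
    DrugSpec("lisinopril", ("Zestril", "Prinivil"), 0.08),
    DrugSpec("atorvastatin", ("Lipitor",), 0.10),
    DrugSpec("ibuprofen", ("Advil", "Motrin"), 0.12),
    DrugSpec("levothyroxine", ("Synthroid",), 0.09),
)

#: Generic -> FDA-approved brand names for the three aromatase inhibitors.
AI_BRANDS = {
    "anastrozole": ("Arimidex",),
    "exemestane": ("Aromasin",),
    "letrozole": ("Femara",),
}


def default_ai_config(n_reports: int = 20_000, seed: int = 0) -> SimulationConfig:
    """Study-shaped default configuration: the three aromatase inhibitors
    (generic + brand spellings) on a female-dominant, age-66-centred
    reporting background, with the study's recurrent dermatologic PTs under
    SOC 10040785 plus non-dermatologic background PTs.

    A handful of derm pairs are planted with elevated odds ratios and Weibull
    onset clocks so every downstream stage (signal scan, time-to-onset,
    regression) has structure to find.
    """
    drugs = [
        DrugSpec("anastrozole", AI_BRANDS["anastrozole"], 0.060, suspect=True),
        DrugSpec("exemestane", AI_BRANDS["exemestane"], 0.030, suspect=True),
        DrugSpec("letrozole", AI_BRANDS["letrozole"], 0.070, suspect=True),
        *_BACKGROUND_DRUGS,
    ]
    pts = [
        *(PtSpec(name, DERM_SOC, "Skin and subcutaneous tissue disorders", p) for name, p in DERM_PTS),
        *(PtSpec(name, soc, soc_name, p) for name, soc, soc_name, p in _BACKGROUND_PTS),
    ]
    planted = [
        PlantedSignal("anastrozole", "Alopecia", 3.0),
        PlantedSignal("anastrozole", "Night sweats", 4.0),
        PlantedSignal("exemestane", "Nail disorder", 5.0),
        PlantedSignal("letrozole", "Nail toxicity", 8.0),
    ]
    onsets = {
        ("anastrozole", "Alopecia"): (1.3, 80.0),
        ("anastrozole", "Night sweats"): (1.1, 28.0),
        ("exemestane", "Nail disorder"): (1.5, 60.0),
        ("exemestane", "Urticaria"): (0.9, 10.0),
        ("letrozole", "Nail toxicity"): (1.4, 90.0),
        ("letrozole", "Urticaria"): (0.8, 3.0),
    }
    return SimulationConfig(
        n_reports=n_reports,
        seed=seed,
        drugs=drugs,
        pts=pts,
        planted_signals=planted,
        onset_models=onsets,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_CASE_STYLES = ("upper", "lower", "title")


def _style(name: str, style: str) -> str:
    if style == "upper":
        return name.upper()
    if style == "lower":
        return name.lower()
    return name.title()


def _quarter_bounds(label: str) -> tuple[np.datetime64, int]:
    year = int(label[:4])
    q = int(label[5])
    start = np.datetime64(f"{year}-{(q - 1) * 3 + 1:02d}-01")
    ndays = {1: 90, 2: 91, 3: 92, 4: 92}[q]
    return start, ndays


def _to_yyyymmdd(days: np.ndarray, origin: np.datetime64) -> np.ndarray:
    """Integer day offsets from ``origin`` -> YYYYMMDD ints."""
    dt = pd.DatetimeIndex(origin + days.astype("timedelta64[D]"))
    return (dt.year * 10000 + dt.month * 100 + dt.day).to_numpy()


def generate_bundle(config: SimulationConfig) -> tuple[QuarterBundle, PlantedTruth]:
    """Draw one synthetic quarter from ``config``.

    Fixed seed gives bit-identical output.  See the module docstring for the
    planting mechanism; the returned truth object carries the exact expected
    2x2 for every planted pair of the pre-duplication stream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    miss = config.missing_rates

    primaryid = 10_000_000 + np.arange(n, dtype=np.int64)
    caseid = 5_000_000 + np.arange(n, dtype=np.int64)

    # --- demographics ------------------------------------------------------
    sexes = list(config.sex_mix)
    sex = rng.choice(sexes, size=n, p=[config.sex_mix[s] for s in sexes])

    young = rng.random(n) < config.age_young_frac
    age_years = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 18.0, 95.0)
    age_years[young] = rng.uniform(2.0, 17.0, size=int(young.sum()))
    unit_names = list(config.age_unit_fracs)
    age_cod = rng.choice(unit_names, size=n, p=[config.age_unit_fracs[u] for u in unit_names])
    age_val = np.round(age_years, 1)
    age_val = np.where(age_cod == "MON", np.round(age_years * 12.0, 1), age_val)
    age_val = np.where(age_cod == "DY", np.round(age_years * 365.25, 0), age_val)

    wt_kg = np.clip(rng.normal(config.wt_mean, config.wt_sd, size=n), 23.0, 176.0)
    use_lbs = rng.random(n) < config.wt_lbs_frac
    wt_cod = np.where(use_lbs, "LBS", "KG")
    wt_val = np.round(np.where(use_lbs, wt_kg / 0.453592, wt_kg), 1)

    occ_names = [k for k in config.occp_mix if k != "UNK"]
    occ_probs = np.array([config.occp_mix[k] for k in occ_names])
    occ_probs = occ_probs / occ_probs.sum()
    occp = rng.choice(occ_names, size=n, p=occ_probs)
    countries = np.where(
        rng.random(n) < config.us_frac,
        "US",
        rng.choice(["GB", "FR", "DE", "JP", "IT", "CA"], size=n),
    )

    # --- drug / PT presence with planted joint structure -------------------
    drug_present: dict[str, np.ndarray] = {
        d.generic: rng.random(n) < d.p for d in config.drugs
    }
    planted_by_pt = {sig.pt: sig for sig in config.planted_signals}
    pt_present: dict[str, np.ndarray] = {}
    for t in config.pts:
        sig = planted_by_pt.get(t.name)
        if sig is None:
            pt_present[t.name] = rng.random(n) < t.p
        else:
            d = config.drug_spec(sig.drug)
            p11 = joint_cell_probability(d.p, t.p, sig.ror_multiplier)
            p_given = p11 / d.p
            p_not = (t.p - p11) / (1.0 - d.p)
            on_drug = drug_present[sig.drug]
            u = rng.random(n)
            pt_present[t.name] = np.where(on_drug, u < p_given, u < p_not)

    # every report mentions at least one drug and one reaction; fallbacks
    # draw only from non-suspect background items so planted margins are
    # untouched
    background_drugs = [d.generic for d in config.drugs if not d.suspect]
    any_drug = np.logical_or.reduce([drug_present[g] for g in drug_present])
    no_drug = ~any_drug
    if no_drug.any() and background_drugs:
        pick = rng.integers(0, len(background_drugs), size=int(no_drug.sum()))
        for j, g in enumerate(background_drugs):
            sel = np.zeros(n, dtype=bool)
            sel[np.flatnonzero(no_drug)[pick == j]] = True
            drug_present[g] |= sel
    background_pts = [t.name for t in config.pts if t.name not in planted_by_pt]
    any_pt = np.logical_or.reduce([pt_present[t] for t in pt_present])
    no_pt = ~any_pt
    if no_pt.any() and background_pts:
        pick = rng.integers(0, len(background_pts), size=int(no_pt.sum()))
        for j, name in enumerate(background_pts):
            sel = np.zeros(n, dtype=bool)
            sel[np.flatnonzero(no_pt)[pick == j]] = True
            pt_present[name] |= sel

    # --- dates -------------------------------------------------------------
    origin, ndays = _quarter_bounds(config.quarter_label)
    fda_days = rng.integers(0, ndays, size=n)
    event_days = fda_days - rng.integers(0, 120, size=n)  # event precedes filing

    # therapy start per (report, drug); default exposure 1-365 d before event
    start_days: dict[str, np.ndarray] = {
        g: event_days - rng.integers(1, 366, size=n) for g in drug_present
    }
    # Weibull onset clocks override: event = start + onset for carrying pairs
    onset_truth: dict[str, dict[str, float]] = {}
    for (g, ptname), (k, lam) in config.onset_models.items():
        onset_truth[PlantedTruth.key(g, ptname)] = {"shape": k, "scale": lam}
        if g not in drug_present or ptname not in pt_present:
            continue
        mask = drug_present[g] & pt_present[ptname]
        m = int(mask.sum())
        if m == 0:
            continue
        onset = np.ceil(lam * rng.weibull(k, size=m)).astype(np.int64)
        onset = np.maximum(onset, 1)
        idx = np.flatnonzero(mask)
        start_days[g][idx] = event_days[idx] - onset

    fda_dt = _to_yyyymmdd(fda_days, origin)
    event_dt = _to_yyyymmdd(event_days, origin).astype(object)
    event_missing = rng.random(n) < miss.get("event_dt", 0.0)
    event_dt[event_missing] = pd.NA

    demo = pd.DataFrame(
        {
            "primaryid": pd.array(primaryid, dtype="Int64"),
            "caseid": pd.array(caseid, dtype="Int64"),
            "fda_dt": pd.array(fda_dt, dtype="Int64"),
            "event_dt": pd.array(event_dt, dtype="Int64"),
            "sex": pd.array(sex, dtype="string"),
            "age": pd.array(np.round(age_val, 2), dtype="Float64"),
            "age_cod": pd.array(age_cod, dtype="string"),
            "wt": pd.array(wt_val, dtype="Float64"),
            "wt_cod": pd.array(wt_cod, dtype="string"),
            "occp_cod": pd.array(occp, dtype="string"),
            "reporter_country": pd.array(countries, dtype="string"),
        }
    )
    for col in ("age", "wt"):
        m = rng.random(n) < miss.get(col, 0.0)
        demo.loc[m, col] = pd.NA
        demo.loc[m, f"{col}_cod"] = pd.NA
    for col in ("occp_cod", "reporter_country"):
        m = rng.random(n) < miss.get(col, 0.0)
        demo.loc[m, col] = pd.NA

    # --- drug & therapy tables --------------------------------------------
    drug_rows = []
    ther_rows = []
    catalog = {d.generic: d for d in config.drugs}
    for g, present in drug_present.items():
        spec = catalog[g]
        idx = np.flatnonzero(present)
        m = len(idx)
        if m == 0:
            continue
        names = [g, *spec.brands]
        name_pick = rng.integers(0, len(names), size=m)
        style_pick = rng.integers(0, len(_CASE_STYLES), size=m)
        spelled = np.array(
            [_style(names[i], _CASE_STYLES[j]) for i, j in zip(name_pick, style_pick)],
            dtype=object,
        )
        prod_ai = np.array([g.upper()] * m, dtype=object)
        prod_ai[rng.random(m) < miss.get("prod_ai", 0.0)] = pd.NA
        role = "PS" if spec.suspect else "C"
        drug_rows.append(
            pd.DataFrame(
                {
                    "row": idx,
                    "generic": g,
                    "drugname": spelled,
                    "prod_ai": prod_ai,
                    "role_cod": role,
                }
            )
        )
        s_missing = rng.random(m) < miss.get("start_dt", 0.0)
        bad = rng.random(m) < config.bad_date_rate
        s_vals = start_days[g][idx].copy()
        # erroneous records: therapy start recorded after the event
        bad_ok = bad & ~s_missing
        s_vals[bad_ok] = event_days[idx][bad_ok] + rng.integers(1, 91, size=int(bad_ok.sum()))
        start_dt = _to_yyyymmdd(s_vals, origin).astype(object)
        start_dt[s_missing] = pd.NA
        end_dt = _to_yyyymmdd(s_vals + rng.integers(30, 301, size=m), origin).astype(object)
        end_dt[rng.random(m) < 0.5] = pd.NA
        ther_rows.append(
            pd.DataFrame({"row": idx, "generic": g, "start_dt": start_dt, "end_dt": end_dt})
        )

    drug_df = pd.concat(drug_rows, ignore_index=True)
    ther_df = pd.concat(ther_rows, ignore_index=True)
    # deterministic within-report ordering: catalog order
    order = {d.generic: i for i, d in enumerate(config.drugs)}
    drug_df["ord"] = drug_df["generic"].map(order)
    drug_df = drug_df.sort_values(["row", "ord"], kind="mergesort").reset_index(drop=True)
    drug_df["drug_seq"] = drug_df.groupby("row").cumcount() + 1
    seq_lookup = drug_df.set_index(["row", "generic"])["drug_seq"]
    ther_df["dsg_drug_seq"] = seq_lookup.loc[
        list(zip(ther_df["row"], ther_df["generic"]))
    ].to_numpy()
    ther_df = ther_df.sort_values(["row", "dsg_drug_seq"], kind="mergesort").reset_index(drop=True)

    drug = pd.DataFrame(
        {
            "primaryid": pd.array(primaryid[drug_df["row"]], dtype="Int64"),
            "caseid": pd.array(caseid[drug_df["row"]], dtype="Int64"),
            "drug_seq": pd.array(drug_df["drug_seq"], dtype="Int64"),
            "role_cod": pd.array(drug_df["role_cod"], dtype="string"),
            "drugname": pd.array(drug_df["drugname"], dtype="string"),
            "prod_ai": pd.array(drug_df["prod_ai"], dtype="string"),
        }
    )
    ther = pd.DataFrame(
        {
            "primaryid": pd.array(primaryid[ther_df["row"]], dtype="Int64"),
            "caseid": pd.array(caseid[ther_df["row"]], dtype="Int64"),
            "dsg_drug_seq": pd.array(ther_df["dsg_drug_seq"], dtype="Int64"),
            "start_dt": pd.array(ther_df["start_dt"], dtype="Int64"),
            "end_dt": pd.array(ther_df["end_dt"], dtype="Int64"),
        }
    )

    # --- reactions ---------------------------------------------------------
    reac_rows = []
    pt_order = {t.name: i for i, t in enumerate(config.pts)}
    for name, present in pt_present.items():
        idx = np.flatnonzero(present)
        if len(idx):
            reac_rows.append(pd.DataFrame({"row": idx, "pt": name, "ord": pt_order[name]}))
    reac_df = (
        pd.concat(reac_rows, ignore_index=True)
        .sort_values(["row", "ord"], kind="mergesort")
        .reset_index(drop=True)
    )
    reac = pd.DataFrame(
        {
            "primaryid": pd.array(primaryid[reac_df["row"]], dtype="Int64"),
            "caseid": pd.array(caseid[reac_df["row"]], dtype="Int64"),
            "pt": pd.array(reac_df["pt"], dtype="string"),
        }
    )

    # --- outcomes ----------------------------------------------------------
    outc_rows = []
    for code in OUTCOME_CODES:
        p = config.outcome_probs.get(code, 0.0)
        idx = np.flatnonzero(rng.random(n) < p)
        if len(idx):
            outc_rows.append(pd.DataFrame({"row": idx, "outc_cod": code}))
    if outc_rows:
        outc_df = (
            pd.concat(outc_rows, ignore_index=True)
            .sort_values(["row", "outc_cod"], kind="mergesort")
            .reset_index(drop=True)
        )
        outc = pd.DataFrame(
            {
                "primaryid": pd.array(primaryid[outc_df["row"]], dtype="Int64"),
                "caseid": pd.array(caseid[outc_df["row"]], dtype="Int64"),
                "outc_cod": pd.array(outc_df["outc_cod"], dtype="string"),
            }
        )
    else:
        outc = pd.DataFrame(
            {
                "primaryid": pd.array([], dtype="Int64"),
                "caseid": pd.array([], dtype="Int64"),
                "outc_cod": pd.array([], dtype="string"),
            }
        )

    # --- duplicate case versions ------------------------------------------
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_idx = np.flatnonzero(dup_mask)
    if len(dup_idx):
        new_pid = primaryid.max() + 1 + np.arange(len(dup_idx), dtype=np.int64)
        pid_map = dict(zip(primaryid[dup_idx].tolist(), new_pid.tolist()))
        dup_demo = demo.iloc[dup_idx].copy()
        dup_demo["primaryid"] = pd.array(new_pid, dtype="Int64")
        # the later version is filed 5-60 days after the original
        later = fda_days[dup_idx] + rng.integers(5, 61, size=len(dup_idx))
        dup_demo["fda_dt"] = pd.array(_to_yyyymmdd(later, origin), dtype="Int64")
        demo = pd.concat([demo, dup_demo], ignore_index=True)

        def _dup(df: pd.DataFrame) -> pd.DataFrame:
            sub = df[df["primaryid"].isin(pid_map)].copy()
            sub["primaryid"] = sub["primaryid"].map(pid_map).astype("Int64")
            return pd.concat([df, sub], ignore_index=True)

        drug, reac, ther, outc = map(_dup, (drug, reac, ther, outc))

    bundle = QuarterBundle(
        demo=demo, drug=drug, reac=reac, ther=ther, outc=outc,
        quarter_label=config.quarter_label,
    )

    truth_tables = {}
    for sig in config.planted_signals:
        d = config.drug_spec(sig.drug)
        t = config.pt_spec(sig.pt)
        a, b, c, dd = expected_cells(n, d.p, t.p, sig.ror_multiplier)
        truth_tables[PlantedTruth.key(sig.drug, sig.pt)] = {
            "a": a, "b": b, "c": c, "d": dd, "ror": sig.ror_multiplier,
        }
    truth = PlantedTruth(n_reports=n, tables=truth_tables, onsets=onset_truth)
    return bundle, truth


# ---------------------------------------------------------------------------
# config file round-trip (for the CLI)
# ---------------------------------------------------------------------------


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    d = asdict(config)
    d["drugs"] = [
        {"generic": x.generic, "brands": list(x.brands), "p": x.p, "suspect": x.suspect}
        for x in config.drugs
    ]
    d["pts"] = [
        {"name": x.name, "soc_code": x.soc_code, "soc_name": x.soc_name, "p": x.p}
        for x in config.pts
    ]
    d["planted_signals"] = [
        {"drug": x.drug, "pt": x.pt, "ror_multiplier": x.ror_multiplier}
        for x in config.planted_signals
    ]
    d["onset_models"] = [
        {"drug": g, "pt": t, "shape": k, "scale": lam}
        for (g, t), (k, lam) in config.onset_models.items()
    ]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path: str | Path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["drugs"] = [
        DrugSpec(x["generic"], tuple(x.get("brands", ())), x["p"], x.get("suspect", False))
        for x in d.get("drugs", [])
    ]
    d["pts"] = [
        PtSpec(x["name"], int(x["soc_code"]), x.get("soc_name", ""), x["p"])
        for x in d.get("pts", [])
    ]
    d["planted_signals"] = [
        PlantedSignal(x["drug"], x["pt"], float(x["ror_multiplier"]))
        for x in d.get("planted_signals", [])
    ]
    d["onset_models"] = {
        (x["drug"], x["pt"]): (float(x["shape"]), float(x["scale"]))
        for x in d.get("onset_models", [])
    }
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg


def write_simulated_quarter(
    config: SimulationConfig, directory: str | Path
) -> tuple[QuarterBundle, PlantedTruth]:
    """Generate and write the five tables plus ``truth.json``."""
    bundle, truth = generate_bundle(config)
    write_bundle(bundle, directory)
    truth.to_json(Path(directory) / "truth.json")
    return bundle, truth
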