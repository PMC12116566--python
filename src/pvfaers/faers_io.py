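"""Reading, writing, deduplication and filtering of FAERS-style quarterly tables.

FAERS quarterly extracts are distributed as ``$``-delimited ASCII tables
(DEMO, DRUG, REAC, THER, OUTC), one record per line with a header row.
This module supports a single canonical dialect of that format: header row,
``$`` separator, no quoting, empty string for a missing field.

Dates are held as YYYYMMDD integers and compared numerically.  A full date
must be a valid calendar day; partial dates (YYYYMM, YYYY) are padded with
``01`` where the consumer only needs an ordering (report-version
deduplication) and treated as missing where day-level arithmetic is required
(time-to-onset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column schemas for the five supported table kinds.  Value is the parse
#: kind: "int", "float", "str", "date_full" (day precision required) or
#: "date_ordering" (partial dates padded to the 1st, used for ordering only).
SCHEMAS: dict[str, dict[str, str]] = {
    "demo": {
        "primaryid": "int",
        "caseid": "int",
        "fda_dt": "date_ordering",
        "event_dt": "date_full",
        "sex": "str",
        "age": "float",
        "age_cod": "str",
        "wt": "float",
        "wt_cod": "str",
        "occp_cod": "str",
        "reporter_country": "str",
    },
    "drug": {
        "primaryid": "int",
        "caseid": "int",
        "drug_seq": "int",
        "role_cod": "str",
        "drugname": "str",
        "prod_ai": "str",
    },
    "reac": {
        "primaryid": "int",
        "caseid": "int",
        "pt": "str",
    },
    "ther": {
        "primaryid": "int",
        "caseid": "int",
        "dsg_drug_seq": "int",
        "start_dt": "date_full",
        "end_dt": "date_full",
    },
    "outc": {
        "primaryid": "int",
        "caseid": "int",
        "outc_cod": "str",
    },
}

#: Conventional file names for a quarter directory.
TABLE_FILES = {
    "demo": "DEMO.txt",
    "drug": "DRUG.txt",
    "reac": "REAC.txt",
    "ther": "THER.txt",
    "outc": "OUTC.txt",
}

DELIM = "$"


class FaersReadError(ValueError):
    """Raised when a table file does not conform to the supported dialect."""


def parse_date_series(raw: pd.Series, *, allow_partial: bool) -> pd.Series:
    """Validate a series of date strings and return YYYYMMDD as ``Int64``.

    ``allow_partial`` pads YYYYMM and YYYY values with ``01`` so they remain
    usable for ordering; otherwise partial dates become missing.  Invalid
    calendar dates always become missing.  Each kind of repair is logged once
    per call with a count.
    """
    s = raw.astype("string").str.strip()
    s = s.mask(s == "", pd.NA)
    digits = s.str.fullmatch(r"\d+", na=False)
    n_nondigit = int((s.notna() & ~digits).sum())
    s = s.where(digits, pd.NA)

    full = s.str.len() == 8
    partial6 = s.str.len() == 6
    partial4 = s.str.len() == 4
    n_partial = int((partial6 | partial4).sum())
    bad_len = s.notna() & ~(full | partial6 | partial4)
    n_badlen = int(bad_len.sum())
    s = s.mask(bad_len, pd.NA)

    if allow_partial:
        s = s.mask(partial6.fillna(False), s + "01")
        s = s.mask(partial4.fillna(False), s + "0101")
        if n_partial:
            logger.warning("padded %d partial date(s) to the 1st for ordering", n_partial)
    else:
        s = s.mask((partial6 | partial4).fillna(False), pd.NA)
        if n_partial:
            logger.warning("dropped %d partial date(s) where day precision is required", n_partial)

    # calendar validity of the (possibly padded) 8-digit values
    parsed = pd.to_datetime(s, format="%Y%m%d", errors="coerce")
    n_invalid = int((s.notna() & parsed.isna()).sum())
    s = s.mask(parsed.isna(), pd.NA)
    if n_invalid or n_nondigit or n_badlen:
        logger.warning(
            "set %d unparseable date value(s) to missing",
            n_invalid + n_nondigit + n_badlen,
        )
    return pd.to_numeric(s, errors="coerce").astype("Int64")


def _convert_column(raw: pd.Series, kind: str) -> pd.Series:
    if kind == "int":
        return pd.to_numeric(raw.replace("", pd.NA), errors="coerce").astype("Int64")
    if kind == "float":
        return pd.to_numeric(raw.replace("", pd.NA), errors="coerce").astype("Float64")
    if kind == "date_full":
        return parse_date_series(raw, allow_partial=False)
    if kind == "date_ordering":
        return parse_date_series(raw, allow_partial=True)
    if kind == "str":
        s = raw.astype("string").str.strip()
        return s.mask(s == "", pd.NA)
    raise AssertionError(f"unknown column kind {kind!r}")


def read_table(path: str | Path, table_kind: str) -> pd.DataFrame:
    """Read one ``$``-delimited FAERS-style table into a typed DataFrame.

    Parameters
    ----------
    path : file path of the table.
    table_kind : one of ``demo``, ``drug``, ``reac``, ``ther``, ``outc``.

    Missing fields (empty strings) map to ``pd.NA``; unparseable dates map to
    missing with a logged warning.  A header missing a schema column raises
    :class:`FaersReadError` naming the column.
    """
    if table_kind not in SCHEMAS:
        raise ValueError(f"unknown table_kind {table_kind!r}; expected one of {sorted(SCHEMAS)}")
    schema = SCHEMAS[table_kind]
    raw = pd.read_csv(
        path,
        sep=DELIM,
        dtype=str,
        keep_default_na=False,
        engine="python",
    )
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing_cols = [c for c in schema if c not in raw.columns]
    if missing_cols:
        raise FaersReadError(
            f"{path}: malformed header for {table_kind} table, missing column(s) {missing_cols}"
        )
    out = pd.DataFrame({col: _convert_column(raw[col], kind) for col, kind in schema.items()})
    return out


def write_table(df: pd.DataFrame, path: str | Path, table_kind: str) -> None:
    """Write a typed table back to the ``$``-delimited dialect (ASCII).

    Missing values are written as empty fields.  ``write_table`` followed by
    :func:`read_table` round-trips all field values.
    """
    if table_kind not in SCHEMAS:
        raise ValueError(f"unknown table_kind {table_kind!r}; expected one of {sorted(SCHEMAS)}")
    schema = SCHEMAS[table_kind]
    cols = [c for c in schema if c in df.columns]
    out = df[cols].copy()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        out.to_csv(fh, sep=DELIM, index=False, na_rep="")


@dataclass
class QuarterBundle:
    """The five FAERS-style tables for one (real or simulated) quarter.

    Invariant: every ``primaryid`` appearing in drug/reac/ther/outc exists in
    ``demo`` (checked by :meth:`validate`).
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    quarter_label: str = "2024Q1"

    def tables(self) -> dict[str, pd.DataFrame]:
        return {k: getattr(self, k) for k in TABLE_FILES}

    def validate(self) -> None:
        known = set(self.demo["primaryid"].dropna().astype(int))
        for kind, df in self.tables().items():
            if kind == "demo":
                continue
            ids = set(df["primaryid"].dropna().astype(int))
            orphans = ids - known
            if orphans:
                raise ValueError(
                    f"{kind} table references primaryid(s) absent from demo, "
                    f"e.g. {sorted(orphans)[:5]}"
                )

    def primaryids(self) -> set[int]:
        return set(self.demo["primaryid"].astype(int))


def read_bundle(directory: str | Path, quarter_label: str = "2024Q1") -> QuarterBundle:
    """Read the five conventional table files from ``directory``."""
    directory = Path(directory)
    tables = {kind: read_table(directory / fname, kind) for kind, fname in TABLE_FILES.items()}
    bundle = QuarterBundle(quarter_label=quarter_label, **tables)
    bundle.validate()
    return bundle


def write_bundle(bundle: QuarterBundle, directory: str | Path) -> None:
    """Write the five tables of ``bundle`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, fname in TABLE_FILES.items():
        write_table(getattr(bundle, kind), directory / fname, kind)


def deduplicate(demo: pd.DataFrame) -> tuple[pd.DataFrame, set[int]]:
    """Collapse report versions to one report per case.

    Among records sharing a CASEID, the report with the most recent FDA_DT is
    retained; ties on FDA_DT are broken by the highest PRIMARYID.  A record
    with missing FDA_DT loses to any dated record of the same case (an
    undated version never displaces a dated one).

    Returns
    -------
    (kept, dropped) : the retained demo rows (one per caseid, original
        column order, sorted by primaryid) and the set of dropped primaryids
        for audit.
    """
    if demo.empty:
        return demo.copy(), set()
    if demo["caseid"].isna().any():
        raise ValueError("deduplicate requires caseid on every record")
    work = demo.copy()
    # missing FDA_DT sorts below every real date
    order_key = work["fda_dt"].fillna(-1).astype("int64")
    work = work.assign(_fda=order_key)
    work = work.sort_values(["caseid", "_fda", "primaryid"], kind="mergesort")
    kept = work.groupby("caseid", sort=False).tail(1).drop(columns="_fda")
    kept = kept.sort_values("primaryid").reset_index(drop=True)
    dropped = set(demo["primaryid"].astype(int)) - set(kept["primaryid"].astype(int))
    return kept, dropped


def restrict_bundle(bundle: QuarterBundle, kept: set[int]) -> QuarterBundle:
    """Filter all five tables of ``bundle`` to the given primaryids.

    ``kept`` must be a subset of the demo table's primaryids; the referential
    invariant of the bundle is preserved.
    """
    universe = bundle.primaryids()
    unknown = set(kept) - universe
    if unknown:
        raise ValueError(f"kept set contains unknown primaryid(s), e.g. {sorted(unknown)[:5]}")
    out = {}
    for kind, df in bundle.tables().items():
        out[kind] = df[df["primaryid"].astype(int).isin(kept)].reset_index(drop=True)
    return QuarterBundle(quarter_label=bundle.quarter_label, **out)


def yyyymmdd_to_datetime(s: pd.Series) -> pd.Series:
    """Convert a YYYYMMDD ``Int64`` series to datetimes (missing-safe)."""
    return pd.to_datetime(s.astype("string"), format="%Y%m%d", errors="coerce")
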