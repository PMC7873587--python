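"""CSV schemas and readers/writers for surveys, ledgers, and reports.

Three documented schemas:

* survey CSV — one row per household per wave, columns
  :data:`cltsce.synthetic.SURVEY_COLUMNS`;
* ledger CSV — long format, columns (arm, region, category, amount_usd,
  hours, rate_usd_per_hour), one row per cost category;
* outcomes CSV — one row per (arm, region) with population sizes,
  deltas, and achieving-household counts.

Readers warn on unknown columns and fail on missing mandatory ones,
naming the column (and row where a value is at fault); write→read
round-trips are lossless.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .costing import CATEGORIES, CostLedger
from .outcomes import OutcomeChange
from .synthetic import SURVEY_COLUMNS

__all__ = [
    "SchemaError",
    "read_survey_csv",
    "write_survey_csv",
    "read_ledger_csv",
    "write_ledger_csv",
    "read_outcomes_csv",
    "write_outcomes_csv",
]

LEDGER_COLUMNS = ["arm", "region", "category", "amount_usd", "hours", "rate_usd_per_hour"]
OUTCOME_COLUMNS = [
    "arm",
    "region",
    "n_households",
    "n_people",
    "delta_od",
    "delta_ownership",
    "households_stopping_od",
    "households_gaining_ownership",
]


class SchemaError(ValueError):
    """An input CSV does not match its documented schema."""


def _check_columns(
    df: pd.DataFrame,
    mandatory: Sequence[str],
    what: str,
    optional: Sequence[str] = (),
) -> None:
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")
    unknown = [c for c in df.columns if c not in mandatory and c not in optional]
    if unknown:
        warnings.warn(f"{what}: ignoring unknown column(s) {unknown}", stacklevel=3)


def read_survey_csv(path) -> pd.DataFrame:
    """Read a household survey table, validating the schema."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty survey file", stacklevel=2)
        return pd.DataFrame(columns=SURVEY_COLUMNS)
    if df.empty:
        warnings.warn(f"{path}: survey file holds no records", stacklevel=2)
        return pd.DataFrame(columns=SURVEY_COLUMNS)
    _check_columns(df, SURVEY_COLUMNS, "survey CSV")
    for col in ("latrine_observed", "latrine_full", "latrine_floor_stable"):
        # robust to bool dtype, "True"/"False" strings, 0/1, and blanks
        df[col] = df[col].map(
            lambda v: str(v).strip().lower() in ("true", "1", "1.0")
        )
    for col in ("n_members",):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"survey CSV: non-numeric value in column {col!r}, row {row}"
            )
    return df[SURVEY_COLUMNS]


def write_survey_csv(df: pd.DataFrame, path) -> None:
    df[SURVEY_COLUMNS].to_csv(path, index=False)


def read_ledger_csv(path) -> List[CostLedger]:
    """Parse a long-format ledger CSV into one ledger per (arm, region).

    Rows carry either a monetized ``amount_usd`` or an (hours, rate)
    pair for the time categories.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty ledger file", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path}: ledger file holds no rows", stacklevel=2)
        return []
    _check_columns(df, LEDGER_COLUMNS[:4], "ledger CSV", optional=LEDGER_COLUMNS[4:])
    ledgers: List[CostLedger] = []
    for (arm, region), grp in df.groupby(["arm", "region"], sort=False):
        kwargs: Dict = {"arm": arm, "region": region}
        for i, row in grp.iterrows():
            cat = row["category"]
            if cat not in CATEGORIES:
                raise SchemaError(
                    f"ledger CSV: unknown category {cat!r} "
                    f"(column 'category', row {i})"
                )
            amount = row.get("amount_usd")
            if pd.notna(amount):
                kwargs[cat] = float(amount)
            if cat in ("local_actor_time", "community_time"):
                prefix = cat.removesuffix("_time")
                hours = row.get("hours")
                rate = row.get("rate_usd_per_hour")
                if pd.notna(hours):
                    kwargs[f"{prefix}_hours"] = float(hours)
                if pd.notna(rate):
                    kwargs[f"{prefix}_rate"] = float(rate)
        ledgers.append(CostLedger(**kwargs))
    return ledgers


def write_ledger_csv(ledgers: Sequence[CostLedger], path) -> None:
    rows = []
    for lg in ledgers:
        for cat, amount in lg.amounts().items():
            prefix = cat.removesuffix("_time")
            rows.append(
                {
                    "arm": lg.arm,
                    "region": lg.region,
                    "category": cat,
                    "amount_usd": amount,
                    "hours": getattr(lg, f"{prefix}_hours", None),
                    "rate_usd_per_hour": getattr(lg, f"{prefix}_rate", None),
                }
            )
    pd.DataFrame(rows, columns=LEDGER_COLUMNS).to_csv(path, index=False)


def read_outcomes_csv(path) -> List[OutcomeChange]:
    df = pd.read_csv(path)
    _check_columns(df, OUTCOME_COLUMNS, "outcomes CSV")
    return [
        OutcomeChange(
            arm=row.arm,
            region=row.region,
            n_households=int(row.n_households),
            n_people=int(row.n_people),
            delta_od=float(row.delta_od),
            delta_ownership=float(row.delta_ownership),
            households_stopping_od=int(row.households_stopping_od),
            households_gaining_ownership=int(row.households_gaining_ownership),
        )
        for row in df.itertuples(index=False)
    ]


def write_outcomes_csv(changes: Sequence[OutcomeChange], path) -> None:
    rows = [
        {col: getattr(c, col) for col in OUTCOME_COLUMNS} for c in changes
    ]
    pd.DataFrame(rows, columns=OUTCOME_COLUMNS).to_csv(path, index=False)
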