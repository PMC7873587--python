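"""Bundled reference tables and regional profiles.

Ships the published cost-category amounts, population and outcome counts
for the four CLTS interventions (two arms per country, five regions,
plus country and pooled roll-up columns), and the regional survey
profiles used to calibrate the synthetic generator.  These printed
tables are the package's primary regression surface, since the raw
survey data were never deposited.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Tuple

import pandas as pd
import yaml

from .costing import CostLedger
from .outcomes import OutcomeChange
from .synthetic import RegionProfile

__all__ = [
    "ARM_REGIONS",
    "LEAF_ARM_REGIONS",
    "load_reference_costs_path",
    "load_reference_ledgers",
    "load_reference_outcomes",
    "load_printed_totals",
    "load_region_profiles",
    "profile_for",
]

Key = Tuple[str, str]

#: All fifteen published arm×region columns, leaves and roll-ups, in
#: presentation order (pooled, Ethiopia, Oromia, SNNP, Ghana, Central,
#: Upper West, Volta).
ARM_REGIONS: list[Key] = [
    ("All CLTS interventions", "All regions"),
    ("HEW CLTS", "Ethiopia"),
    ("Teacher CLTS", "Ethiopia"),
    ("HEW CLTS", "Oromia"),
    ("Teacher CLTS", "Oromia"),
    ("HEW CLTS", "SNNP"),
    ("Teacher CLTS", "SNNP"),
    ("NGO CLTS", "Ghana"),
    ("CLTS + NL Training", "Ghana"),
    ("NGO CLTS", "Central"),
    ("CLTS + NL Training", "Central"),
    ("NGO CLTS", "Upper West"),
    ("CLTS + NL Training", "Upper West"),
    ("NGO CLTS", "Volta"),
    ("CLTS + NL Training", "Volta"),
]

#: The eight leaf (single-arm, single-region) columns.
LEAF_ARM_REGIONS: list[Key] = [
    (a, r)
    for (a, r) in ARM_REGIONS
    if r not in ("All regions", "Ethiopia", "Ghana")
]

#: Which leaf columns roll up into each aggregate column.
ROLLUP_MEMBERS: Dict[Key, list[Key]] = {
    ("HEW CLTS", "Ethiopia"): [("HEW CLTS", "Oromia"), ("HEW CLTS", "SNNP")],
    ("Teacher CLTS", "Ethiopia"): [
        ("Teacher CLTS", "Oromia"),
        ("Teacher CLTS", "SNNP"),
    ],
    ("NGO CLTS", "Ghana"): [
        ("NGO CLTS", "Central"),
        ("NGO CLTS", "Upper West"),
        ("NGO CLTS", "Volta"),
    ],
    ("CLTS + NL Training", "Ghana"): [
        ("CLTS + NL Training", "Central"),
        ("CLTS + NL Training", "Upper West"),
        ("CLTS + NL Training", "Volta"),
    ],
    ("All CLTS interventions", "All regions"): LEAF_ARM_REGIONS,
}

#: Months from intervention start to follow-up survey, by country.
FOLLOWUP_WINDOW_MONTHS = {"Ethiopia": 24.0, "Ghana": 30.0}


def _data_path(name: str):
    return resources.files("cltsce.data").joinpath(name)


def load_reference_costs_path() -> str:
    """Filesystem path of the bundled ledger CSV (long schema)."""
    return str(_data_path("reference_costs.csv"))


def load_reference_ledgers() -> Dict[Key, CostLedger]:
    """The fifteen published cost columns as ledgers keyed (arm, region)."""
    from .io import read_ledger_csv

    ledgers = read_ledger_csv(load_reference_costs_path())
    return {(lg.arm, lg.region): lg for lg in ledgers}


def load_reference_outcomes() -> Dict[Key, OutcomeChange]:
    """Published population sizes, outcome deltas and achieving-household
    counts, keyed (arm, region).

    Counts are the printed integers (the published table derived them
    from unrounded fractions, so they are *not* recomputable from the
    rounded percentage deltas also shipped here).
    """
    df = pd.read_csv(_data_path("reference_outcomes.csv"))
    out: Dict[Key, OutcomeChange] = {}
    for row in df.itertuples(index=False):
        out[(row.arm, row.region)] = OutcomeChange(
            arm=row.arm,
            region=row.region,
            n_households=int(row.n_households),
            n_people=int(row.n_people),
            delta_od=float(row.delta_od),
            delta_ownership=float(row.delta_ownership),
            households_stopping_od=int(row.households_stopping_od),
            households_gaining_ownership=int(row.households_gaining_ownership),
        )
    return out


def load_printed_totals() -> Dict[Key, float]:
    """Published whole-dollar total-cost cells, keyed (arm, region)."""
    df = pd.read_csv(_data_path("reference_totals.csv"))
    return {
        (row.arm, row.region): float(row.total_usd)
        for row in df.itertuples(index=False)
    }


def load_region_profiles() -> Dict[str, RegionProfile]:
    """Calibrated regional profiles (deltas default to the conventional
    CLTS arm in each region)."""
    with open(_data_path("region_profiles.yaml")) as fh:
        raw = yaml.safe_load(fh)
    return {name: RegionProfile(**fields) for name, fields in raw.items()}


def profile_for(region: str, arm: str) -> RegionProfile:
    """Regional profile with the effect sizes of a specific arm.

    Published baselines are region-wide while effect sizes are per arm,
    so a large arm-specific delta can overshoot a margin bound (e.g. a
    +53% ownership gain on a 51% pooled baseline); such deltas are
    clamped to the feasible range with a warning.
    """
    import warnings

    profiles = load_region_profiles()
    if region not in profiles:
        raise KeyError(f"unknown region: {region!r}")
    change = load_reference_outcomes().get((arm, region))
    if change is None:
        raise KeyError(f"no published outcomes for {arm!r} in {region!r}")
    p = profiles[region]
    d_od = min(max(change.delta_od, -p.baseline_od), 1.0 - p.baseline_od)
    d_own = min(
        max(change.delta_ownership, -p.baseline_ownership),
        1.0 - p.baseline_ownership,
    )
    if (d_od, d_own) != (change.delta_od, change.delta_ownership):
        warnings.warn(
            f"{arm}/{region}: effect size clamped to the feasible range "
            f"of the region-wide baseline margins",
            stacklevel=2,
        )
    return p.replace(delta_od=d_od, delta_ownership=d_own)
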