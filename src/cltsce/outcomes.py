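"""Household outcome classification and change computation.

Two household-level outcomes are measured.  *Open defecation* (OD):
latrine use counts reported private, shared, or communal latrines, but a
reported private latrine is validated by observation — households whose
latrine was full, had unstable flooring, or could not be observed are
reclassified as OD.  *Usable latrine ownership*: a household owns a
usable latrine only if one was observed on survey day with stable
flooring and not full.

Changes are follow-up minus baseline fractions; achieving-household
counts are derived from the unrounded fractions and then rounded half
away from zero (printed percentages are rounded, so counts recomputed
from them drift; the unrounded chain matches published count cells).
Worsening outcomes yield negative counts, which are retained and
flagged, never clipped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeChange",
    "classify_usable_latrine",
    "classify_defecation",
    "classify_survey",
    "recall_baseline_ownership",
    "conservative_baseline_od",
    "compute_outcome_change",
    "pool_outcome_changes",
    "round_half_away",
]

_PRACTICES = {
    "open_defecation",
    "private_latrine",
    "shared_latrine",
    "communal_latrine",
}


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _get(record, name, default=None):
    # accept dataclasses, pandas Series/rows, and plain dicts
    if isinstance(record, dict):
        v = record.get(name, default)
    else:
        v = getattr(record, name, default)
    if v is None:
        return default
    if isinstance(v, float) and math.isnan(v):
        return default
    return v


def classify_usable_latrine(record) -> bool:
    """True iff a usable latrine was observed for this household.

    Usable means: observed on survey day, stable flooring, not full.
    Missing observation fields count as not usable.
    """
    return (
        bool(_get(record, "latrine_observed", False))
        and bool(_get(record, "latrine_floor_stable", False))
        and not bool(_get(record, "latrine_full", True))
    )


def classify_defecation(record) -> str:
    """Classify a household as ``open_defecation`` or ``latrine_use``.

    Shared and communal latrine use counts as latrine use.  A reported
    private latrine counts only if it passes :func:`classify_usable_latrine`;
    otherwise the household is reclassified as OD.
    """
    practice = _get(record, "reported_practice")
    if practice not in _PRACTICES:
        raise ValueError(f"unknown reported_practice: {practice!r}")
    if practice == "open_defecation":
        return "open_defecation"
    if practice in ("shared_latrine", "communal_latrine"):
        return "latrine_use"
    return "latrine_use" if classify_usable_latrine(record) else "open_defecation"


def classify_survey(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification of a survey table.

    Returns a copy with two boolean columns: ``od`` (classified open
    defecation) and ``owns_usable`` (usable latrine observed).
    """
    bad = ~df["reported_practice"].isin(_PRACTICES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown reported_practice {df['reported_practice'].iloc[row]!r} "
            f"(column 'reported_practice', row {row})"
        )
    observed = df["latrine_observed"].fillna(False).astype(bool)
    stable = df["latrine_floor_stable"].fillna(False).astype(bool)
    full = df["latrine_full"].fillna(True).astype(bool)
    usable = observed & stable & ~full
    practice = df["reported_practice"]
    od = (practice == "open_defecation") | ((practice == "private_latrine") & ~usable)
    out = df.copy()
    out["od"] = od
    out["owns_usable"] = usable
    return out


def recall_baseline_ownership(
    followup: pd.DataFrame, months_since_start: float
) -> float:
    """Estimate baseline usable-latrine ownership from latrine-age recall.

    Used where no baseline survey exists (the Ghana design): a household
    counted as a baseline owner iff its currently usable latrine predates
    the intervention, i.e. ``latrine_age_months > months_since_start``.

    Raises
    ------
    ValueError
        If no latrine-owning household carries an age recall.
    """
    cls = classify_survey(followup)
    owners = cls[cls["owns_usable"]]
    if len(owners) == 0:
        return 0.0
    if owners["latrine_age_months"].isna().all():
        raise ValueError(
            "recall-based baseline estimation needs latrine_age_months "
            "for latrine-owning households; all are missing"
        )
    pre_existing = (owners["latrine_age_months"] > months_since_start).sum()
    return float(pre_existing) / len(cls)


class ConservativeBaseline(NamedTuple):
    """Assumption-derived baseline OD estimate (decrease in OD taken
    equal to the increase in latrine ownership)."""

    value: float
    assumed: bool = True
    clamped: bool = False


def conservative_baseline_od(
    followup_od: float, delta_ownership: float
) -> ConservativeBaseline:
    """Baseline OD under the conservative no-baseline-survey assumption.

    Assumes the decrease in OD equals the increase in latrine ownership,
    so baseline OD = follow-up OD + delta_ownership, clamped to [0, 1].
    """
    raw = followup_od + delta_ownership
    value = min(1.0, max(0.0, raw))
    clamped = value != raw
    if clamped:
        warnings.warn(
            f"conservative baseline OD {raw:.3f} clamped to {value:.1f}",
            stacklevel=2,
        )
    return ConservativeBaseline(value=value, clamped=clamped)


@dataclass(frozen=True)
class OutcomeChange:
    """Changes in the two sanitation outcomes for one arm and region.

    ``delta_od`` and ``delta_ownership`` are signed follow-up-minus-
    baseline fractions.  Counts follow the convention that a *decrease*
    in OD is a positive number of households stopping OD.
    """

    arm: str
    region: str
    n_households: int
    n_people: int
    delta_od: float
    delta_ownership: float
    households_stopping_od: int
    households_gaining_ownership: int

    def __post_init__(self) -> None:
        if self.n_households <= 0:
            raise ValueError("n_households must be > 0")
        if abs(self.delta_od) > 1 or abs(self.delta_ownership) > 1:
            raise ValueError("outcome deltas must lie in [-1, 1]")

    @property
    def worsened(self) -> dict:
        """Outcome measures whose change went the wrong way."""
        flags = {}
        if self.households_stopping_od < 0:
            flags["stopped_od"] = self.households_stopping_od
        if self.households_gaining_ownership < 0:
            flags["gained_ownership"] = self.households_gaining_ownership
        return flags

    @property
    def mean_household_size(self) -> float:
        return self.n_people / self.n_households

    @classmethod
    def from_fractions(
        cls,
        arm: str,
        region: str,
        n_households: int,
        n_people: int,
        delta_od: float,
        delta_ownership: float,
    ) -> "OutcomeChange":
        """Derive achieving-household counts from unrounded fractions."""
        return cls(
            arm=arm,
            region=region,
            n_households=n_households,
            n_people=n_people,
            delta_od=delta_od,
            delta_ownership=delta_ownership,
            households_stopping_od=round_half_away(-delta_od * n_households),
            households_gaining_ownership=round_half_away(
                delta_ownership * n_households
            ),
        )


def _wave_fractions(df: pd.DataFrame) -> tuple[float, float]:
    cls = classify_survey(df)
    return float(cls["od"].mean()), float(cls["owns_usable"].mean())


def compute_outcome_change(
    baseline: Union[pd.DataFrame, tuple],
    followup: pd.DataFrame,
    arm: str | None = None,
    region: str | None = None,
) -> OutcomeChange:
    """Compute outcome changes between a baseline and a follow-up wave.

    ``baseline`` is either a survey table (measured-baseline mode) or an
    ``(od_fraction, ownership_fraction)`` pair (estimated-baseline mode,
    e.g. from :func:`recall_baseline_ownership` /
    :func:`conservative_baseline_od`).  Both waves must cover the same
    arm and region; counts are derived from unrounded deltas.
    """
    if len(followup) == 0:
        raise ValueError("follow-up wave holds zero households")
    f_od, f_own = _wave_fractions(followup)
    if isinstance(baseline, pd.DataFrame):
        if len(baseline) == 0:
            raise ValueError("baseline wave holds zero households")
        b_od, b_own = _wave_fractions(baseline)
        b_arms = set(baseline["arm"]) | set(baseline["region"])
        f_arms = set(followup["arm"]) | set(followup["region"])
        if b_arms != f_arms:
            raise ValueError(
                f"waves cover different arm/region scopes: {b_arms} vs {f_arms}"
            )
    else:
        b_od, b_own = float(baseline[0]), float(baseline[1])
    arm = arm if arm is not None else str(followup["arm"].iloc[0])
    region = region if region is not None else str(followup["region"].iloc[0])
    change = OutcomeChange.from_fractions(
        arm=arm,
        region=region,
        n_households=int(followup["household_id"].nunique()),
        n_people=int(followup["n_members"].sum()),
        delta_od=f_od - b_od,
        delta_ownership=f_own - b_own,
    )
    if change.worsened:
        warnings.warn(
            f"{arm}/{region}: outcomes worsened for {sorted(change.worsened)}",
            stacklevel=2,
        )
    return change


def pool_outcome_changes(
    changes: list[OutcomeChange], arm: str, region: str
) -> OutcomeChange:
    """Household-weighted pooling of regional outcome changes."""
    if not changes:
        raise ValueError("nothing to pool")
    n_hh = sum(c.n_households for c in changes)
    n_people = sum(c.n_people for c in changes)
    d_od = sum(c.delta_od * c.n_households for c in changes) / n_hh
    d_own = sum(c.delta_ownership * c.n_households for c in changes) / n_hh
    return OutcomeChange(
        arm=arm,
        region=region,
        n_households=n_hh,
        n_people=n_people,
        delta_od=d_od,
        delta_ownership=d_own,
        households_stopping_od=sum(c.households_stopping_od for c in changes),
        households_gaining_ownership=sum(
            c.households_gaining_ownership for c in changes
        ),
    )
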