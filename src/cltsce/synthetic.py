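"""Synthetic household-survey panels and cost ledgers.

The study this package emulates surveyed rural households in Ethiopia and
Ghana before and after community-led total sanitation (CLTS) facilitation,
recording reported defecation practice, direct latrine observations
(flooring stability, whether the pit was full), latrine age, and household
spending on sanitation.  No raw survey data were deposited, so this module
generates panels with the same statistical structure — regional baseline
margins for open defecation (OD) and usable-latrine ownership, panel
transitions matching the published effect sizes, and right-skewed
household spending — letting every downstream stage run and be tested
without any download.

Two classification margins drive the design.  A household is *classified
OD* if it reports open defecation or reports a private latrine that
observation invalidates (full, unstable flooring, or not observable); it
is *classified an owner* if a usable private latrine was observed on
survey day.  The generator draws the two margins independently per
household (contradictory cells such as "reports OD but a usable latrine
stands in the yard" are legal and occur in real data), then realizes
survey fields so that the downstream classifier recovers exactly the
intended margins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RegionProfile",
    "HouseholdRecord",
    "SURVEY_COLUMNS",
    "generate_households",
    "generate_cost_ledger",
]

#: Documented column order of the household-survey table (one row per
#: household per wave).
SURVEY_COLUMNS = [
    "household_id",
    "village_id",
    "region",
    "arm",
    "n_members",
    "survey_wave",
    "reported_practice",
    "latrine_observed",
    "latrine_full",
    "latrine_floor_stable",
    "latrine_age_months",
    "hardware_spend",
    "hired_labor_spend",
    "sanitation_hours",
]

PRACTICES = ("open_defecation", "private_latrine", "shared_latrine", "communal_latrine")


class ProfileValidationError(ValueError):
    """A region profile field is outside its legal range."""


@dataclass(frozen=True)
class RegionProfile:
    """Statistical profile of one study region.

    Fractions are household-level probabilities; ``delta_od`` and
    ``delta_ownership`` are signed follow-up-minus-baseline changes
    (a negative ``delta_od`` means open defecation fell).
    """

    region_name: str
    n_villages: int
    mean_village_size: float
    household_size_mean: float
    household_size_sd: float
    baseline_ownership: float
    baseline_od: float
    delta_od: float = 0.0
    delta_ownership: float = 0.0
    shared_use_fraction: float = 0.2
    unusable_fraction: float = 0.15
    hardware_spend_mean: float = 2.0
    hired_labor_spend_mean: float = 1.0
    community_hours_mean: float = 2.0
    #: Optional within-village correlation of the OD outcome (intraclass
    #: correlation of the baseline OD indicator); 0 = none.
    village_icc: float = 0.0

    def __post_init__(self) -> None:
        for field in (
            "baseline_ownership",
            "baseline_od",
            "shared_use_fraction",
            "unusable_fraction",
            "village_icc",
        ):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise ProfileValidationError(
                    f"{field}={v!r} must be a fraction in [0, 1]"
                )
        for field in ("delta_od", "delta_ownership"):
            if not -1.0 <= getattr(self, field) <= 1.0:
                raise ProfileValidationError(f"{field} must lie in [-1, 1]")
        if not 0.0 <= self.baseline_od + self.delta_od <= 1.0:
            raise ProfileValidationError(
                "delta_od drives follow-up OD outside [0, 1]"
            )
        if not 0.0 <= self.baseline_ownership + self.delta_ownership <= 1.0:
            raise ProfileValidationError(
                "delta_ownership drives follow-up ownership outside [0, 1]"
            )
        if self.household_size_mean <= 0:
            raise ProfileValidationError("household_size_mean must be > 0")
        if self.household_size_sd < 0:
            raise ProfileValidationError("household_size_sd must be >= 0")
        if self.n_villages < 1:
            raise ProfileValidationError("n_villages must be >= 1")
        for field in (
            "hardware_spend_mean",
            "hired_labor_spend_mean",
            "community_hours_mean",
        ):
            if getattr(self, field) < 0:
                raise ProfileValidationError(f"{field} must be >= 0")

    def replace(self, **changes) -> "RegionProfile":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household in one wave (row of the survey table)."""

    household_id: str
    village_id: str
    region: str
    arm: str
    n_members: int
    survey_wave: str  # "baseline" | "followup"
    reported_practice: str
    latrine_observed: bool = False
    latrine_full: bool = False
    latrine_floor_stable: bool = False
    latrine_age_months: Optional[float] = None
    hardware_spend: float = 0.0
    hired_labor_spend: float = 0.0
    sanitation_hours: float = 0.0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        for field in ("hardware_spend", "hired_labor_spend", "sanitation_hours"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")


def _transition(state: np.ndarray, delta: float, base: float, rng) -> np.ndarray:
    """Flip a Bernoulli state vector so its mean moves by ``delta``.

    ``state`` holds the *positive* condition (e.g. latrine use, ownership)
    with baseline prevalence ``base``.  Gains are realized among the
    at-risk negatives with probability delta/(1-base); losses among the
    positives with probability -delta/base, so the marginal flip
    probability is exactly |delta|.
    """
    out = state.copy()
    if delta > 0 and base < 1.0:
        flip = (~state) & (rng.random(state.size) < delta / (1.0 - base))
        out[flip] = True
    elif delta < 0 and base > 0.0:
        flip = state & (rng.random(state.size) < -delta / base)
        out[flip] = False
    return out


def _skewed_spend(rng, n: int, spender: np.ndarray, mean_total: float) -> np.ndarray:
    """Zero-inflated lognormal spending: zeros except for ``spender``
    households, with the overall mean equal to ``mean_total``."""
    out = np.zeros(n)
    k = int(spender.sum())
    if k == 0 or mean_total <= 0:
        return out
    # lognormal with sigma=1; scale so the full-sample mean hits target
    draws = rng.lognormal(mean=0.0, sigma=1.0, size=k)
    draws *= (mean_total * n) / draws.sum()
    out[spender] = draws
    return out


def _realize_wave(
    rng,
    profile: RegionProfile,
    use: np.ndarray,
    owner: np.ndarray,
    owner_prev: Optional[np.ndarray],
    window_months: float,
) -> dict:
    """Turn classified states into raw survey fields.

    The inverse of the outcomes-module classifier: ``use`` (latrine use
    vs OD) is encoded in reported_practice, ``owner`` (usable private
    latrine) in the observation fields, such that classification of the
    returned fields reproduces the inputs exactly.
    """
    n = use.size
    practice = np.full(n, "open_defecation", dtype=object)
    observed = np.zeros(n, dtype=bool)
    full = np.zeros(n, dtype=bool)
    stable = np.zeros(n, dtype=bool)
    age = np.full(n, np.nan)

    u = rng.random(n)
    shared_kind = np.where(rng.random(n) < 0.7, "shared_latrine", "communal_latrine")

    # users who own a usable latrine report it as private (minus the
    # shared-use fraction, who use a neighbour's or communal facility)
    private = use & owner & (u >= profile.shared_use_fraction)
    practice[private] = "private_latrine"
    practice[use & ~private] = shared_kind[use & ~private]

    # classified-OD non-owners: a slice reports a private latrine that
    # observation invalidates (full / unstable / not observable)
    od = ~use
    bad_reporter = od & ~owner & (rng.random(n) < profile.unusable_fraction)
    practice[bad_reporter] = "private_latrine"
    mode = rng.integers(0, 3, size=n)  # 0 unobserved, 1 full, 2 unstable
    m1 = bad_reporter & (mode == 1)
    m2 = bad_reporter & (mode == 2)
    observed[m1 | m2] = True
    full[m1] = True
    stable[m1] = True
    full[m2] = False
    stable[m2] = False

    # owners: usable latrine observed regardless of reported practice
    observed[owner] = True
    full[owner] = False
    stable[owner] = True

    if owner_prev is None:  # baseline wave: pre-existing stock
        age[owner] = rng.uniform(window_months, 120.0, size=int(owner.sum()))
    else:
        kept = owner & owner_prev
        new = owner & ~owner_prev
        age[kept] = rng.uniform(window_months, 120.0, size=int(kept.sum())) + window_months
        age[new] = rng.uniform(0.0, window_months, size=int(new.sum()))
    return {
        "reported_practice": practice,
        "latrine_observed": observed,
        "latrine_full": full,
        "latrine_floor_stable": stable,
        "latrine_age_months": age,
    }


def generate_households(
    profile: RegionProfile,
    n: int,
    seed: int,
    arm: str = "CLTS",
    window_months: float = 24.0,
) -> pd.DataFrame:
    """Generate a two-wave household panel for one region.

    Parameters
    ----------
    profile
        Regional margins and effect sizes.
    n
        Number of households (each contributes a baseline and a
        follow-up row).
    seed
        Seed for the generator; a (profile, n, seed) triple fully
        determines the output.
    arm
        Intervention label stamped on every record.
    window_months
        Months from intervention start to the follow-up survey (24 for
        the Ethiopia design, 30 for Ghana); bounds new-latrine ages.

    Returns
    -------
    pandas.DataFrame
        ``SURVEY_COLUMNS`` schema, 2n rows (baseline wave then
        follow-up), same household ids in both waves.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return pd.DataFrame(columns=SURVEY_COLUMNS)
    rng = np.random.default_rng(seed)

    hid = np.array([f"{profile.region_name}-h{i:06d}" for i in range(n)], dtype=object)
    village_idx = rng.integers(0, profile.n_villages, size=n)
    vid = np.array(
        [f"{profile.region_name}-v{j:03d}" for j in village_idx], dtype=object
    )
    members = np.maximum(
        1,
        np.rint(
            rng.normal(profile.household_size_mean, profile.household_size_sd, size=n)
        ),
    ).astype(int)

    # baseline margins; optional village-level random effect on OD
    p_od = profile.baseline_od
    if profile.village_icc > 0 and 0 < p_od < 1:
        icc = profile.village_icc
        a = p_od * (1 - icc) / icc
        b = (1 - p_od) * (1 - icc) / icc
        village_p = rng.beta(a, b, size=profile.n_villages)
        p_od_i = village_p[village_idx]
    else:
        p_od_i = np.full(n, p_od)
    use0 = rng.random(n) >= p_od_i
    owner0 = rng.random(n) < profile.baseline_ownership

    use1 = _transition(use0, -profile.delta_od, 1.0 - p_od, rng)
    owner1 = _transition(
        owner0, profile.delta_ownership, profile.baseline_ownership, rng
    )

    base_fields = _realize_wave(rng, profile, use0, owner0, None, window_months)
    follow_fields = _realize_wave(rng, profile, use1, owner1, owner0, window_months)

    new_owner = owner1 & ~owner0
    hardware = _skewed_spend(rng, n, new_owner, profile.hardware_spend_mean)
    hired = _skewed_spend(rng, n, new_owner, profile.hired_labor_spend_mean)
    hours_mask = new_owner | (rng.random(n) < 0.25)
    hours = _skewed_spend(rng, n, hours_mask, profile.community_hours_mean)

    def wave_frame(wave: str, fields: dict, hw, hl, hrs) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "household_id": hid,
                "village_id": vid,
                "region": profile.region_name,
                "arm": arm,
                "n_members": members,
                "survey_wave": wave,
                "hardware_spend": hw,
                "hired_labor_spend": hl,
                "sanitation_hours": hrs,
                **fields,
            }
        )

    zeros = np.zeros(n)
    out = pd.concat(
        [
            wave_frame("baseline", base_fields, zeros, zeros, zeros),
            wave_frame("followup", follow_fields, hardware, hired, hours),
        ],
        ignore_index=True,
    )
    return out[SURVEY_COLUMNS]


def generate_cost_ledger(
    arm: str,
    region: str,
    totals: dict,
    jitter: float = 0.0,
    seed: int = 0,
):
    """Build a cost ledger from per-category totals, optionally perturbed.

    With ``jitter`` = 0 the ledger equals ``totals`` exactly; otherwise
    each category is scaled by an independent Uniform(1-jitter, 1+jitter)
    factor.  Categories missing from ``totals`` default to 0.
    """
    from .costing import CATEGORIES, CostLedger

    if not 0.0 <= jitter < 1.0:
        raise ValueError("jitter must lie in [0, 1)")
    unknown = set(totals) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown cost categories: {sorted(unknown)}")
    for cat, v in totals.items():
        if v < 0:
            raise ValueError(f"negative total for {cat}: {v}")
    rng = np.random.default_rng(seed)
    factors = rng.uniform(1.0 - jitter, 1.0 + jitter, size=len(CATEGORIES))
    amounts = {
        cat: float(totals.get(cat, 0.0)) * (factors[i] if jitter > 0 else 1.0)
        for i, cat in enumerate(CATEGORIES)
    }
    return CostLedger(arm=arm, region=region, **amounts)
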