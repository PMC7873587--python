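"""Bottom-up activity-based societal costing.

Costs take the societal perspective: *program* costs borne by the
implementing organization (management, training, facilitation — measured
from activity tracking and expenditure review) plus *local* costs borne
by local actors and households (local-actor time, community-member time,
hired labor, latrine hardware).  Unpaid time is monetized at a
value-of-time rate derived from local wages.  Amounts are nominal USD of
the study period; no discount rate is applied (costs span only two
years).  Internally amounts keep cent-level precision; report writers
round to whole dollars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

__all__ = [
    "CATEGORIES",
    "PROGRAM_CATEGORIES",
    "LOCAL_CATEGORIES",
    "CostLedger",
    "CostBreakdown",
    "monetize_time",
    "total_cost",
    "aggregate_ledgers",
]

PROGRAM_CATEGORIES = ("management", "training", "facilitation")
LOCAL_CATEGORIES = ("local_actor_time", "community_time", "hired_labor", "hardware")
#: The seven cost categories, program first.
CATEGORIES = PROGRAM_CATEGORIES + LOCAL_CATEGORIES


def monetize_time(hours: float, rate: float) -> float:
    """Value of unpaid time: hours × value-of-time rate (USD/hour)."""
    if hours < 0:
        raise ValueError(f"hours must be >= 0, got {hours}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return hours * rate


@dataclass
class CostLedger:
    """Societal costs of one intervention arm in one region.

    Time categories may be supplied pre-monetized (as published tables
    report them) or as (hours, rate) pairs; when both are present the
    monetized amount wins and a mismatch is warned about.
    """

    arm: str
    region: str
    management: float = 0.0
    training: float = 0.0
    facilitation: float = 0.0
    local_actor_time: Optional[float] = None
    community_time: Optional[float] = None
    hired_labor: float = 0.0
    hardware: float = 0.0
    local_actor_hours: Optional[float] = None
    local_actor_rate: Optional[float] = None
    community_hours: Optional[float] = None
    community_rate: Optional[float] = None
    extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name in ("local_actor", "community"):
            monetized = getattr(self, f"{name}_time")
            hours = getattr(self, f"{name}_hours")
            rate = getattr(self, f"{name}_rate")
            if hours is not None and rate is not None:
                computed = monetize_time(hours, rate)
                if monetized is None:
                    setattr(self, f"{name}_time", computed)
                elif abs(monetized - computed) > 0.01:
                    warnings.warn(
                        f"{self.arm}/{self.region}: {name}_time ${monetized:,.2f} "
                        f"differs from hours×rate ${computed:,.2f}; "
                        "keeping the monetized value",
                        stacklevel=3,
                    )
            elif monetized is None:
                setattr(self, f"{name}_time", 0.0)
        for cat in CATEGORIES:
            v = getattr(self, cat)
            if v < 0:
                raise ValueError(f"{self.arm}/{self.region}: {cat} must be >= 0")

    def amounts(self) -> dict:
        """Category → amount (USD) mapping in canonical order."""
        return {cat: float(getattr(self, cat)) for cat in CATEGORIES}


class CostBreakdown(NamedTuple):
    """Total cost with its program/local split (USD)."""

    program: float
    local: float
    total: float


def total_cost(ledger: CostLedger) -> CostBreakdown:
    """Sum the seven categories; undiscounted nominal USD."""
    program = sum(getattr(ledger, c) for c in PROGRAM_CATEGORIES)
    local = sum(getattr(ledger, c) for c in LOCAL_CATEGORIES)
    return CostBreakdown(program=program, local=local, total=program + local)


def aggregate_ledgers(
    ledgers: Sequence[CostLedger],
    arm: Optional[str] = None,
    region: Optional[str] = None,
) -> CostLedger:
    """Category-wise sum of ledgers (region → country → study roll-ups).

    Labels default to the single shared value, or ``"combined"`` when
    the inputs mix several arms or regions.
    """
    ledgers = list(ledgers)
    if not ledgers:
        raise ValueError("cannot aggregate an empty collection of ledgers")

    def _label(values, override):
        if override is not None:
            return override
        uniq = sorted({v for v in values})
        return uniq[0] if len(uniq) == 1 else "combined"

    sums = {cat: sum(lg.amounts()[cat] for lg in ledgers) for cat in CATEGORIES}
    return CostLedger(
        arm=_label((lg.arm for lg in ledgers), arm),
        region=_label((lg.region for lg in ledgers), region),
        **sums,
    )
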