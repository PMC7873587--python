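"""Cost-effectiveness and incremental cost-effectiveness ratios.

The core statistic is CE = Cost / Outcome: total societal cost divided
by the number of households achieving the outcome (stopping open
defecation, or gaining ownership of a usable latrine), interpreted as
the societal cost to convert one household.  The counterfactual is no
change absent the intervention.  Where an outcome worsened the ratio
would be negative and misleading, so the result is carried as
undefined-with-a-note rather than a number (mirroring suppressed table
cells) — never as an exception.

ICERs compare two arms on the same outcome and population:
(cost_B − cost_A) / (outcome_B − outcome_A), with the usual dominance
quadrants of the CE plane labeled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

__all__ = ["CEResult", "ICERResult", "cost_effectiveness", "per_person", "icer"]

OUTCOME_MEASURES = ("stopped_od", "gained_ownership")


@dataclass(frozen=True)
class CEResult:
    """A cost-effectiveness ratio, possibly undefined.

    ``defined`` is False when the outcome count is zero or negative; the
    ratio fields are then ``None`` and ``note`` says why.
    """

    arm: str
    region: str
    outcome_measure: str
    total_cost: float
    outcome_count: int
    ce_per_household: Optional[float]
    ce_per_person: Optional[float]
    defined: bool
    note: str = ""


def cost_effectiveness(
    total_cost: float,
    outcome_count: int,
    outcome_measure: str,
    arm: str = "",
    region: str = "",
    n_people: Optional[int] = None,
    n_households: Optional[int] = None,
) -> CEResult:
    """Societal cost per household achieving an outcome.

    Pass ``n_people`` and ``n_households`` to also populate the
    per-person scale (per-household CE divided by mean household size).
    """
    if total_cost < 0:
        raise ValueError("total_cost must be >= 0")
    if outcome_measure not in OUTCOME_MEASURES:
        raise ValueError(f"unknown outcome measure: {outcome_measure!r}")
    if outcome_count <= 0:
        note = (
            "outcome worsened; negative ratio suppressed"
            if outcome_count < 0
            else "no households achieved the outcome"
        )
        return CEResult(
            arm=arm,
            region=region,
            outcome_measure=outcome_measure,
            total_cost=total_cost,
            outcome_count=outcome_count,
            ce_per_household=None,
            ce_per_person=None,
            defined=False,
            note=note,
        )
    per_hh = total_cost / outcome_count
    per_pp = None
    if n_people is not None and n_households is not None and n_households > 0:
        per_pp = per_hh / (n_people / n_households)
    return CEResult(
        arm=arm,
        region=region,
        outcome_measure=outcome_measure,
        total_cost=total_cost,
        outcome_count=outcome_count,
        ce_per_household=per_hh,
        ce_per_person=per_pp,
        defined=True,
    )


def per_person(ce: CEResult, n_people: int, n_households: int) -> CEResult:
    """Attach the per-person scale: per-household CE ÷ mean household size.

    An undefined CE propagates unchanged.
    """
    if not ce.defined:
        return ce
    if n_people <= 0 or n_households <= 0:
        raise ValueError("population counts must be > 0")
    return replace(ce, ce_per_person=ce.ce_per_household / (n_people / n_households))


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost per additional unit of outcome, with its
    dominance-quadrant label."""

    value: Optional[float]
    delta_cost: float
    delta_outcome: int
    label: str
    note: str = ""


def icer(
    reference: Tuple[float, int], comparator: Tuple[float, int]
) -> ICERResult:
    """ICER of ``comparator`` over ``reference`` on a shared outcome.

    Both arguments are ``(total_cost, outcome_count)`` pairs measured on
    the same outcome and population.  Quadrants: a comparator that is
    cheaper *and* more effective is "dominant"; costlier and less
    effective is "dominated"; equal outcomes give an undefined ratio.
    """
    ref_cost, ref_out = reference
    cmp_cost, cmp_out = comparator
    d_cost = cmp_cost - ref_cost
    d_out = cmp_out - ref_out
    if d_out == 0:
        return ICERResult(
            value=None,
            delta_cost=d_cost,
            delta_outcome=0,
            label="undefined",
            note="no incremental effect",
        )
    value = d_cost / d_out
    if d_out > 0:
        label = "dominant" if d_cost < 0 else "more effective, more costly"
    else:
        label = "dominated" if d_cost > 0 else "less effective, cheaper"
    return ICERResult(value=value, delta_cost=d_cost, delta_outcome=d_out, label=label)
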