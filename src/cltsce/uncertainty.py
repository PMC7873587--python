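"""Monte Carlo probabilistic sensitivity analysis (PSA) of CE ratios.

Costs were measured rather than estimated, so each of the seven cost
categories gets an independent Uniform(±30%) distribution around its
base value as a conservative spread.  Outcome changes get normal
distributions; where no empirical standard deviation is available the
fallback is 50% of the point estimate (the convention used where impact-
evaluation SDs were missing).  Each draw recomputes total cost, the
achieving-household count, and the CE ratio; the 95% interval is the
empirical 2.5th–97.5th percentile of the *defined* draws (outcome > 0),
with the lower bound floored at zero.  Draws whose outcome goes
non-positive are excluded from the percentiles but reported as
``fraction_undefined_draws`` — the Monte Carlo analogue of suppressing
negative ratios.

Parameters are drawn independently; no cost–outcome correlation is
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .cea import cost_effectiveness
from .costing import CATEGORIES, CostLedger, total_cost
from .outcomes import OutcomeChange

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "OverlapReport",
    "default_specs",
    "sample_draw",
    "run_psa",
    "overlap_report",
]

DEFAULT_COST_HALF_WIDTH = 0.30
DEFAULT_SD_FALLBACK = 0.50
DEFAULT_N_DRAWS = 1000


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one uncertain parameter.

    ``uniform_relative`` draws from center×(1±half_width_relative);
    ``normal`` draws from N(center, sd), with sd defaulting to
    ``sd_fallback_fraction`` × |center| when not supplied.
    """

    parameter: str
    kind: str  # "uniform_relative" | "normal"
    center: float
    half_width_relative: Optional[float] = None
    sd: Optional[float] = None
    sd_fallback_fraction: float = DEFAULT_SD_FALLBACK

    def __post_init__(self) -> None:
        if self.kind == "uniform_relative":
            w = self.half_width_relative
            if w is None or not 0.0 <= w < 1.0:
                raise ValueError(
                    f"{self.parameter}: half_width_relative must lie in [0, 1)"
                )
        elif self.kind == "normal":
            if self.sd is not None and self.sd < 0:
                raise ValueError(f"{self.parameter}: sd must be >= 0")
        else:
            raise ValueError(f"{self.parameter}: unknown distribution {self.kind!r}")

    @property
    def effective_sd(self) -> float:
        if self.sd is not None:
            return self.sd
        return self.sd_fallback_fraction * abs(self.center)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "uniform_relative":
            w = self.half_width_relative
            return self.center * rng.uniform(1.0 - w, 1.0 + w, size=size)
        sd = self.effective_sd
        if sd == 0:
            return np.full(size, self.center)
        return rng.normal(self.center, sd, size=size)


def default_specs(
    ledger: CostLedger,
    change: OutcomeChange,
    cost_half_width: float = DEFAULT_COST_HALF_WIDTH,
    od_sd: Optional[float] = None,
    ownership_sd: Optional[float] = None,
    sd_fallback_fraction: float = DEFAULT_SD_FALLBACK,
) -> list[DistributionSpec]:
    """The stated-assumption spec set: ±30% uniform on every cost
    category, normal on each outcome delta."""
    specs = [
        DistributionSpec(
            parameter=f"cost:{cat}",
            kind="uniform_relative",
            center=amount,
            half_width_relative=cost_half_width,
        )
        for cat, amount in ledger.amounts().items()
    ]
    specs.append(
        DistributionSpec(
            parameter="outcome:delta_od",
            kind="normal",
            center=change.delta_od,
            sd=od_sd,
            sd_fallback_fraction=sd_fallback_fraction,
        )
    )
    specs.append(
        DistributionSpec(
            parameter="outcome:delta_ownership",
            kind="normal",
            center=change.delta_ownership,
            sd=ownership_sd,
            sd_fallback_fraction=sd_fallback_fraction,
        )
    )
    return specs


def sample_draw(
    specs: Sequence[DistributionSpec], rng: np.random.Generator
) -> dict:
    """One independent draw of every parameter (parameter → value)."""
    return {s.parameter: float(s.sample(rng, 1)[0]) for s in specs}


@dataclass(frozen=True)
class PSAResult:
    """Summary of one Monte Carlo PSA for one outcome measure."""

    arm: str
    region: str
    outcome_measure: str
    point_estimate: Optional[float]
    n_draws: int
    ci_low: float
    ci_high: float
    fraction_undefined_draws: float
    seed: int
    draws: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def interval(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def _outcome_center_and_sign(change: OutcomeChange, measure: str) -> tuple[str, float]:
    # OD decreases are the achievement, so the count flips sign
    if measure == "stopped_od":
        return "outcome:delta_od", -1.0
    return "outcome:delta_ownership", 1.0


def run_psa(
    ledger: CostLedger,
    change: OutcomeChange,
    specs: Optional[Sequence[DistributionSpec]] = None,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    outcome_measures: Sequence[str] = ("stopped_od", "gained_ownership"),
) -> Dict[str, PSAResult]:
    """Monte Carlo PSA of the CE ratios for one arm/region.

    Per draw: every cost category and outcome delta is redrawn from its
    spec, total cost and the achieving-household count recomputed, and
    CE formed where the count is positive.  Returns one
    :class:`PSAResult` per outcome measure.

    Raises
    ------
    RuntimeError
        If every draw of a measure is undefined
        (``fraction_undefined_draws`` = 1).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if specs is None:
        specs = default_specs(ledger, change)
    rng = np.random.default_rng(seed)
    draws = {s.parameter: s.sample(rng, n_draws) for s in specs}

    cost_params = [p for p in draws if p.startswith("cost:")]
    if cost_params:
        cost_draws = np.sum([draws[p] for p in cost_params], axis=0)
    else:
        cost_draws = np.full(n_draws, total_cost(ledger).total)

    results: Dict[str, PSAResult] = {}
    for measure in outcome_measures:
        param, sign = _outcome_center_and_sign(change, measure)
        if param in draws:
            raw = sign * draws[param] * change.n_households
            # households are integers: same half-away-from-zero rounding
            # as the point-estimate chain, so degenerate draws reproduce it
            counts = np.copysign(np.floor(np.abs(raw) + 0.5), raw)
        else:
            base = (
                change.households_stopping_od
                if measure == "stopped_od"
                else change.households_gaining_ownership
            )
            counts = np.full(n_draws, float(base))
        defined = counts > 0
        frac_undef = 1.0 - defined.mean()
        if not defined.any():
            raise RuntimeError(
                f"{measure}: all {n_draws} draws undefined "
                f"(fraction_undefined_draws = 1.0)"
            )
        ce_draws = cost_draws[defined] / counts[defined]
        lo, hi = np.percentile(ce_draws, [2.5, 97.5], method="linear")
        point = cost_effectiveness(
            total_cost(ledger).total,
            (
                change.households_stopping_od
                if measure == "stopped_od"
                else change.households_gaining_ownership
            ),
            measure,
            arm=ledger.arm,
            region=ledger.region,
        )
        results[measure] = PSAResult(
            arm=ledger.arm,
            region=ledger.region,
            outcome_measure=measure,
            point_estimate=point.ce_per_household,
            n_draws=n_draws,
            ci_low=max(0.0, float(lo)),
            ci_high=float(hi),
            fraction_undefined_draws=float(frac_undef),
            seed=seed,
            draws=ce_draws,
        )
    return results


@dataclass(frozen=True)
class OverlapReport:
    overlap: bool
    summary: str


def overlap_report(a: PSAResult, b: PSAResult) -> OverlapReport:
    """Do two 95% intervals on the same outcome measure intersect?

    Overlapping intervals mean the simulations do not indicate that one
    intervention is more cost effective than the other.
    """
    if a.outcome_measure != b.outcome_measure:
        raise ValueError("intervals compare only on a shared outcome measure")
    overlap = a.ci_low <= b.ci_high and b.ci_low <= a.ci_high
    verdict = "overlap" if overlap else "do not overlap"
    summary = (
        f"{a.arm}/{a.region} [{a.ci_low:,.2f}, {a.ci_high:,.2f}] and "
        f"{b.arm}/{b.region} [{b.ci_low:,.2f}, {b.ci_high:,.2f}] {verdict} "
        f"({a.outcome_measure})"
    )
    return OverlapReport(overlap=overlap, summary=summary)
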