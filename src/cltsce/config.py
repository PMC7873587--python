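"""Analysis configuration.

A config is a plain YAML or JSON mapping (YAML is a superset of JSON, so
one loader serves both).  With no file at all the defaults reproduce the
bundled published-table analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

__all__ = ["AnalysisConfig", "PSASettings"]


@dataclass
class PSASettings:
    n_draws: int = 1000
    seed: int = 0
    cost_half_width: float = 0.30
    sd_fallback_fraction: float = 0.50
    enabled: bool = True


@dataclass
class AnalysisConfig:
    """End-to-end pipeline settings.

    ``ledger_path`` / ``outcomes_path`` default to the bundled reference
    tables; ``survey_path`` switches the outcome stage to classifying a
    household survey instead of using pre-tabulated outcome changes.
    """

    arms: Optional[Sequence[str]] = None  # None = every arm in the inputs
    regions: Optional[Sequence[str]] = None
    ledger_path: Optional[str] = None
    outcomes_path: Optional[str] = None
    survey_path: Optional[str] = None
    outcome_measures: Sequence[str] = ("stopped_od", "gained_ownership")
    psa: PSASettings = field(default_factory=PSASettings)
    output_dir: str = "cltsce_report"

    def __post_init__(self) -> None:
        if not self.outcome_measures:
            raise ValueError("select at least one outcome measure")
        bad = set(self.outcome_measures) - {"stopped_od", "gained_ownership"}
        if bad:
            raise ValueError(f"unknown outcome measure(s): {sorted(bad)}")
        if isinstance(self.psa, dict):
            self.psa = PSASettings(**self.psa)
        for name in ("ledger_path", "outcomes_path", "survey_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file: {p}")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)
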