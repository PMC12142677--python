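"""Workflow configuration.

Defaults are the workflow's standard operating parameters: 0.03 Da /
2-bin alignment tolerances, 1.5-fold-change and 0.1 p-value differential
cuts, a +-1% CCS filtering threshold, 0.005 Da / 5 ppm database tolerances
and top-20 candidate ingestion.  Unknown keys are rejected on load so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

__all__ = ["WorkflowConfig"]


@dataclass
class WorkflowConfig:
    # alignment tolerances
    mz_tol_da: float = 0.03
    drift_tol_bins: float = 2.0
    # differential statistics
    fc_threshold: float = 1.5
    p_threshold: float = 0.1
    # CCS candidate filtering
    ccs_threshold_pct: float = 1.0
    tie_window_pct: float = 0.05
    # database matching (absolute-Da and ppm conventions)
    db_tol_da: float = 0.005
    db_tol_ppm: float = 5.0
    top_k_candidates: int = 20
    adducts: Tuple[str, ...] = ("[M+H]+", "[M+Na]+", "[M+K]+", "[M+2H]2+")
    # instrument constants
    pusher_period_us: float = 64.0
    edc_coefficient: float = 1.41
    edc_unit_factor: float = 1.0
    drift_gas_mass: float = 28.00615
    # reproducibility
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        positive = (
            "mz_tol_da",
            "drift_tol_bins",
            "fc_threshold",
            "ccs_threshold_pct",
            "db_tol_da",
            "db_tol_ppm",
            "pusher_period_us",
            "drift_gas_mass",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.top_k_candidates < 1:
            raise ValueError("top_k_candidates must be >= 1")
        self.adducts = tuple(self.adducts)

    @classmethod
    def from_dict(cls, data: dict) -> "WorkflowConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "WorkflowConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adducts"] = list(self.adducts)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
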