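"""Pipeline configuration: one flat record of every tunable parameter."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .smoothing import DEFAULT_LAMBDA_GRID


@dataclass
class PipelineConfig:
    """All knobs of the analysis pipeline, with study defaults.

    ``bonferroni_n`` is a constant (171) rather than recomputed: the exact
    correlation inventory behind the multiplicity correction is fixed by
    the analysis design, not by the data at hand.
    """

    n_basis: int = 7
    n_fpc: int = 3
    lambda_grid: list[float] = field(
        default_factory=lambda: [float(x) for x in DEFAULT_LAMBDA_GRID]
    )
    quadrature_step: float = 1.0  # minutes
    seed: int = 0
    bonferroni_alpha: float = 0.05
    bonferroni_n: int = 171
    fpg_gt: float = 100.0   # dysglycemia if FPG strictly above, mg/dL
    pg2h_gt: float = 140.0  # ... or 2-h glucose strictly above, mg/dL
    shape_delta: float = 4.5  # mg/dL drop/re-rise threshold

    def validate(self) -> None:
        if self.n_fpc < 1:
            raise ValueError("n_fpc must be >= 1")
        if self.n_basis < self.n_fpc + 1:
            raise ValueError("n_basis must be >= n_fpc + 1")
        grid = np.asarray(self.lambda_grid, float)
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError("lambda_grid must be non-empty and positive")
        for name in ("quadrature_step", "fpg_gt", "pg2h_gt", "shape_delta",
                     "bonferroni_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bonferroni_n < 1:
            raise ValueError("bonferroni_n must be >= 1")

    @property
    def bonferroni_threshold(self) -> float:
        return self.bonferroni_alpha / self.bonferroni_n

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
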