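"""Shared containers used across the screening, clinical and meta-analysis stages.

Only light validation lives here; the statistical contracts are enforced by the
functions that consume these types.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ArmSummary:
    """Per-arm summary statistics: sample size, mean and SD of a marker.

    Units follow the source table (RPM for sequencing cohorts, platform
    intensity or delta-Ct-derived units for microarray/qPCR studies).
    """

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"arm needs n >= 2, got {self.n}")
        if self.sd < 0 or not np.isfinite(self.sd):
            raise ValidationError(f"arm SD must be finite and >= 0, got {self.sd}")
        if not np.isfinite(self.mean):
            raise ValidationError("arm mean must be finite")


@dataclass(frozen=True)
class StudyRow:
    """One two-arm study: case (diseased) and control arms plus metadata."""

    study_id: str
    case: ArmSummary
    control: ArmSummary
    sample_type: str = "tissue"
    source: str = ""


@dataclass(frozen=True)
class EffectSize:
    """Standardized mean difference with its sampling variance."""

    d: float
    var: float
    flavor: str = "cohen"

    def __post_init__(self) -> None:
        if self.var <= 0 or not np.isfinite(self.var):
            raise ValidationError(f"effect-size variance must be > 0, got {self.var}")

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var))


@dataclass(frozen=True)
class Diag2x2:
    """2x2 diagnostic accuracy counts for a single study."""

    study_id: str
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name} must be a nonnegative integer, got {v}")
        if self.tp + self.fn < 1:
            raise ValidationError("diseased margin (tp + fn) must be >= 1")
        if self.fp + self.tn < 1:
            raise ValidationError("healthy margin (fp + tn) must be >= 1")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn


@dataclass
class ExpressionCohort:
    """Expression matrix (features x samples) with per-sample group labels.

    ``values`` is a DataFrame whose index holds feature (miRNA) names and whose
    columns are sample identifiers; ``sample_groups`` maps every sample column
    to a group label.  Values are nonnegative expression measurements (RPM or
    microarray intensities).
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_groups = pd.Series(self.sample_groups)
        missing = [c for c in self.values.columns if c not in self.sample_groups.index]
        if missing:
            raise ValidationError(f"samples without group labels: {missing[:5]}")
        if self.sample_groups.isna().any():
            raise ValidationError("missing group labels")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValidationError("expression values must be finite")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.sample_groups))

    def samples_in(self, group: str) -> list[str]:
        idx = self.sample_groups[self.sample_groups == group].index
        return [s for s in self.values.columns if s in set(idx)]
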