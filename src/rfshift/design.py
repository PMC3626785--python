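"""Design-matrix container shared by the cohort, forest and importance layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DesignMatrix:
    """Complete-case numeric design for one regression fit.

    ``column_groups`` maps each original variable to the encoded columns it
    contributed (one-hot categoricals expand to several); numeric variables
    map to themselves.  Used to aggregate importances back to the original
    variables.
    """

    predictor_names: list[str]
    X: np.ndarray
    y: np.ndarray
    model_spec: object | None = None
    visit: int | None = None
    group: str | None = None
    column_groups: dict[str, list[str]] = field(default_factory=dict)
    patient_ids: list | None = None

    def __post_init__(self):
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        self.y = np.ascontiguousarray(self.y, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.predictor_names):
            raise ValueError("predictor_names inconsistent with X")
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y row counts differ")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("design must be complete-case (no NaN)")
        if not self.column_groups:
            self.column_groups = {n: [n] for n in self.predictor_names}

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]
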