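"""Model specifications: which QoL scores predict the MusiQoL global index.

Two nested specifications are analysed per (visit, disability-change group):

  M1: GlobalIndex = f(PCS, MCS, X)                 — the two SF-36 composites
  M2: GlobalIndex = f(PF, RP, Vi, BP, SF, RE, MH, GH, X)  — the eight scales

with X the baseline covariates (age, gender, education level, marital
status, employment status, disease duration).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ModelSpec:
    name: str
    qol_predictors: tuple[str, ...]
    include_covariates: bool = True

    def __post_init__(self):
        if self.name not in ("M1", "M2"):
            raise ValueError("model name must be 'M1' or 'M2'")


M1 = ModelSpec("M1", ("pcs", "mcs"))
M2 = ModelSpec("M2", ("pf", "rp", "vitality", "bp", "sf", "re", "mh", "gh"))


def model_by_name(name: str, include_covariates: bool = True) -> ModelSpec:
    base = {"M1": M1, "M2": M2}[name.upper()]
    return ModelSpec(base.name, base.qol_predictors, include_covariates)
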