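"""Reprioritization detection from crossing AVI trajectories.

For each disability-change group and model, a random forest predicting the
MusiQoL global index is fit at every visit M0..M24 and the averaged
permutation importance (AVI) of each predictor is recorded, yielding one
importance trajectory per variable.  Reprioritization is flagged for a
variable pair (a, b) — by default the MCS/MCS composites (mcs, pcs) — when
their AVI curves cross over time in the worsened group but not in the
not-worsened control group, which is assumed free of response shift.

Crossings are read off the piecewise-linear interpolant of the five AVI
points: with D(t) = avi_a(t) - avi_b(t), an interval (t, t+1) contains a
crossing iff D(t) * D(t+1) < 0, at interpolated time
t + D(t) / (D(t) - D(t+1)).  An exact tie D(t) = 0 is a "touch", reported
separately and not counted as a crossing.  No formal significance test is
attached; per-visit AVI standard deviations are surfaced so users can judge
curve separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import NOT_WORSENED, WORSENED, CohortTable, build_design_matrix
from .errors import EmptyDesignError
from .forest import ForestParams
from .importance import AVIResult, average_vi
from .models import M1, M2, ModelSpec

__all__ = ["ModelSpec", "M1", "M2", "AVITrajectory", "Crossing",
           "GroupCrossings", "CrossingReport", "compute_avi_trajectories",
           "detect_crossings", "reprioritization_analysis", "DEFAULT_PAIR"]

DEFAULT_PAIR = ("mcs", "pcs")
# headline comparison per model: the mental/physical composites under M1,
# the mental-health vs physical-functioning scales under M2
DEFAULT_PAIRS = {"M1": ("mcs", "pcs"), "M2": ("mh", "pf")}
VISITS = (0, 1, 2, 3, 4)


@dataclass
class AVITrajectory:
    """Per-visit AVI results for one (model, group)."""

    model: ModelSpec
    group: str
    per_visit: dict[int, AVIResult]
    variance_explained: dict[int, float]
    gaps: list[int] = field(default_factory=list)

    def series(self, variable: str) -> dict[int, float]:
        return {t: r.avi[variable] for t, r in self.per_visit.items()}

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "group": self.group,
            "gaps": list(self.gaps),
            "variance_explained": {str(t): v for t, v
                                   in self.variance_explained.items()},
            "avi": {str(t): r.avi for t, r in self.per_visit.items()},
            "sd": {str(t): r.sd for t, r in self.per_visit.items()},
            "K": next(iter(self.per_visit.values())).K if self.per_visit else 0,
        }


@dataclass(frozen=True)
class Crossing:
    interval: tuple[int, int]
    time: float

    def to_dict(self):
        return {"interval": list(self.interval), "time": self.time}


@dataclass
class GroupCrossings:
    """Crossing scan of one group's AVI trajectories for a variable pair."""

    pair: tuple[str, str]
    crossings: list[Crossing]
    touches: list[int]               # visits with an exact tie D(t) = 0
    skipped_intervals: list[tuple[int, int]]

    @property
    def crosses(self) -> bool:
        return len(self.crossings) > 0

    def to_dict(self):
        return {"pair": list(self.pair),
                "crossings": [c.to_dict() for c in self.crossings],
                "touches": list(self.touches),
                "skipped_intervals": [list(i) for i in self.skipped_intervals]}


@dataclass
class CrossingReport:
    """Two-group comparison: reprioritization iff the worsened curves cross
    and the control curves do not."""

    variable_pair: tuple[str, str]
    worsened: GroupCrossings
    control: GroupCrossings
    worsened_crosses: bool
    control_crosses: bool
    reprioritization_flag: bool
    avi_ratio_by_visit: dict[str, dict[int, float | None]]
    trajectories: dict[str, AVITrajectory] | None = None

    def to_dict(self):
        d = {
            "variable_pair": list(self.variable_pair),
            "worsened": self.worsened.to_dict(),
            "control": self.control.to_dict(),
            "worsened_crosses": self.worsened_crosses,
            "control_crosses": self.control_crosses,
            "reprioritization_flag": self.reprioritization_flag,
            "avi_ratio_by_visit": {g: {str(t): v for t, v in r.items()}
                                   for g, r in self.avi_ratio_by_visit.items()},
        }
        if self.trajectories is not None:
            d["trajectories"] = {g: t.to_dict()
                                 for g, t in self.trajectories.items()}
        return d


def compute_avi_trajectories(cohort: CohortTable, model: ModelSpec,
                             group: str, params: ForestParams,
                             K: int = 300, seed: int = 0) -> AVITrajectory:
    """AVI at every visit M0..M24 for one group and model.

    The same master seed drives every visit's forest runs (visits differ by
    their data, so reusing the stream costs no independence and makes the
    trajectory of a time-constant cohort exactly flat).  Visits with no
    complete cases are recorded as gaps; crossing detection skips gapped
    intervals.
    """
    per_visit, ve, gaps = {}, {}, []
    for t in VISITS:
        try:
            design = build_design_matrix(cohort, t, group, model)
        except EmptyDesignError:
            gaps.append(t)
            continue
        res = average_vi(design, params, K=K, master_seed=seed)
        per_visit[t] = res
        ve[t] = res.variance_explained_mean
    return AVITrajectory(model=model, group=group, per_visit=per_visit,
                         variance_explained=ve, gaps=gaps)


def detect_crossings(traj: AVITrajectory,
                     pair: tuple[str, str]) -> GroupCrossings:
    """Scan one trajectory for sign changes of avi_a(t) - avi_b(t)."""
    a, b = pair
    visits = sorted(traj.per_visit)
    if len(visits) < 2:
        raise EmptyDesignError(
            "need at least 2 visits with AVI results to detect crossings")
    delta = {t: traj.per_visit[t].avi[a] - traj.per_visit[t].avi[b]
             for t in visits}
    touches = [t for t in visits if delta[t] == 0.0]
    crossings, skipped = [], []
    for t in VISITS[:-1]:
        if t not in delta or t + 1 not in delta:
            if t in traj.gaps or t + 1 in traj.gaps:
                skipped.append((t, t + 1))
            continue
        d0, d1 = delta[t], delta[t + 1]
        if d0 * d1 < 0.0:
            crossings.append(Crossing((t, t + 1), t + d0 / (d0 - d1)))
    return GroupCrossings(pair=pair, crossings=crossings, touches=touches,
                          skipped_intervals=skipped)


def _ratios(traj: AVITrajectory, pair):
    a, b = pair
    out = {}
    for t, res in sorted(traj.per_visit.items()):
        denom = res.avi[b]
        out[t] = float(res.avi[a] / denom) if denom != 0 else None
    return out


def reprioritization_analysis(cohort: CohortTable, model: ModelSpec = M1,
                              pair: tuple[str, str] = DEFAULT_PAIR,
                              params: ForestParams = ForestParams(),
                              K: int = 300, seed: int = 0) -> CrossingReport:
    """Full two-group analysis for one model and variable pair.

    Fits AVI trajectories for the worsened and not-worsened (control)
    groups with independent seed substreams, scans both for crossings, and
    flags reprioritization iff the worsened curves cross while the control
    curves do not.  Per-visit AVI ratios avi_a / avi_b are reported for both
    groups.
    """
    s_w, s_c = np.random.SeedSequence(seed).spawn(2)
    seeds = {
        WORSENED: int(s_w.generate_state(1, np.uint64)[0] & 0x7FFFFFFF),
        NOT_WORSENED: int(s_c.generate_state(1, np.uint64)[0] & 0x7FFFFFFF),
    }
    trajs = {g: compute_avi_trajectories(cohort, model, g, params, K=K,
                                         seed=seeds[g])
             for g in (WORSENED, NOT_WORSENED)}
    worsened = detect_crossings(trajs[WORSENED], pair)
    control = detect_crossings(trajs[NOT_WORSENED], pair)
    return CrossingReport(
        variable_pair=pair, worsened=worsened, control=control,
        worsened_crosses=worsened.crosses, control_crosses=control.crosses,
        reprioritization_flag=worsened.crosses and not control.crosses,
        avi_ratio_by_visit={g: _ratios(trajs[g], pair) for g in trajs},
        trajectories=trajs)
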