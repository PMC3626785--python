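"""Synthetic longitudinal MS cohorts with controllable reprioritization.

The generator emulates the statistical structure the detection pipeline
assumes: correlated SF-36 domain scores evolving with AR(1) persistence
across five six-monthly visits, norm-based PCS/MCS composites, a MusiQoL
global index driven by *time-varying domain weights* (the generative stand-
in for reprioritization), baseline covariates and EDSS trajectories matching
the published cohort marginals (age ~ N(41.3, 10.2) truncated at 18, 72.2%
female, baseline EDSS ~ N(2.9, 1.9) on the half-point grid, ~20% worsened
at 24 months), and EDSS progressions constructed so that the disability-
change classifier reproduces each patient's intended group exactly.

Two named scenarios drive validation:

* ``control_scenario``      — constant weights in both groups (mental
  cluster more important than physical), the no-response-shift null.
* ``reprioritization_scenario`` — the worsened group's mental-cluster
  weights decline and physical-cluster weights rise linearly in time,
  crossing exactly at ``crossing_time``; the control group keeps constant
  weights.  ``strength`` scales the worsened group's weight contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (NOT_WORSENED, WORSENED, CohortTable,
                     classify_disability_change)
from .errors import SimulationError

__all__ = ["SimulationConfig", "simulate_cohort", "control_scenario",
           "reprioritization_scenario", "DOMAINS", "PHYSICAL_DOMAINS",
           "MENTAL_DOMAINS", "default_domain_corr"]

DOMAINS = ("pf", "rp", "bp", "gh", "vitality", "sf", "re", "mh")
PHYSICAL_DOMAINS = ("pf", "rp", "bp", "gh")
MENTAL_DOMAINS = ("vitality", "sf", "re", "mh")
N_VISITS = 5
MUSIQOL_DIMENSIONS = ("adl", "pwb", "rfr", "spt", "rfa", "rhcs", "ssl",
                      "cop", "rej")  # nine MusiQoL dimensions


def default_domain_corr(within: float = 0.5, between: float = 0.25):
    """Block correlation: physical and mental clusters of four domains."""
    p = len(DOMAINS)
    corr = np.full((p, p), between)
    for cluster in (PHYSICAL_DOMAINS, MENTAL_DOMAINS):
        idx = [DOMAINS.index(d) for d in cluster]
        for i in idx:
            for j in idx:
                corr[i, j] = within
    np.fill_diagonal(corr, 1.0)
    return corr


def _constant_weights(contrast: float) -> dict:
    w = {}
    for d in MENTAL_DOMAINS:
        w[d] = np.full(N_VISITS, 1.0 + contrast)
    for d in PHYSICAL_DOMAINS:
        w[d] = np.full(N_VISITS, 1.0 - contrast)
    return w


@dataclass
class SimulationConfig:
    """Generator conditions; defaults reproduce the published cohort split.

    ``weight_curves`` maps group -> domain -> length-5 nonnegative weight
    vector; weights are normalized to sum to one over domains at each visit
    before forming the index.  ``noise_sd`` is residual SD on the 0-100
    index scale; ``index_gain`` converts the standardized weighted domain
    combination to index points.
    """

    n_worsened: int = 107
    n_not_worsened: int = 417
    weight_curves: dict = field(default_factory=lambda: {
        WORSENED: _constant_weights(0.3),
        NOT_WORSENED: _constant_weights(0.3)})
    domain_corr: np.ndarray = field(default_factory=default_domain_corr)
    ar1_rho: float = 0.7
    noise_sd: float = 8.0
    index_gain: float = 18.0
    age_mean: float = 41.3
    age_sd: float = 10.2
    p_female: float = 0.722
    education_probs: tuple = (0.195, 0.140, 0.665)
    p_cohabiting: float = 0.678
    p_employed: float = 0.578
    duration_mean: float = 10.0
    duration_sd: float = 7.5
    edss_mean: float = 2.9
    edss_sd: float = 1.9
    edss_max: float = 7.5
    edss_physical_effect: float = 2.5   # index points per EDSS step, physical
    edss_mental_effect: float = 1.0
    domain_base: float = 72.0
    domain_scale: float = 15.0
    tscore_mean: float = 50.0
    tscore_sd: float = 10.0
    emit_dimensions: bool = False
    missing_rate: float = 0.0
    seed: int = 0
    crossing_time: float | None = None  # metadata set by scenario builders
    scenario: str = "custom"

    def validate(self):
        for g in (WORSENED, NOT_WORSENED):
            for d in DOMAINS:
                w = np.asarray(self.weight_curves[g][d], float)
                if w.shape != (N_VISITS,) or (w < 0).any():
                    raise SimulationError(
                        f"weight curve {g}/{d} must be 5 nonnegative values")
        for t in range(N_VISITS):
            for g in (WORSENED, NOT_WORSENED):
                tot = sum(float(self.weight_curves[g][d][t]) for d in DOMAINS)
                if tot <= 0:
                    raise SimulationError(
                        f"all weights zero at visit {t} for group {g}")
        corr = np.asarray(self.domain_corr, float)
        if corr.shape != (len(DOMAINS),) * 2 or not np.allclose(corr, corr.T):
            raise SimulationError("domain_corr must be symmetric 8x8")
        if not np.allclose(np.diag(corr), 1.0):
            raise SimulationError("domain_corr diagonal must be 1")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise SimulationError("domain_corr must be positive semi-definite")

    def truth(self) -> dict:
        """Ground-truth parameters for recovery tests (the simulator oracle)."""
        return {
            "scenario": self.scenario,
            "crossing_time": self.crossing_time,
            "weight_curves": {
                g: {d: [float(v) for v in self.weight_curves[g][d]]
                    for d in DOMAINS}
                for g in (WORSENED, NOT_WORSENED)},
            "domain_corr_within": float(self.domain_corr[0, 1]),
            "domain_corr_between": float(self.domain_corr[0, -1]),
            "ar1_rho": self.ar1_rho,
            "noise_sd": self.noise_sd,
            "index_gain": self.index_gain,
            "n_worsened": self.n_worsened,
            "n_not_worsened": self.n_not_worsened,
            "seed": self.seed,
        }


def control_scenario(n_worsened: int = 107, n_not_worsened: int = 417,
                     contrast: float = 0.3, seed: int = 0,
                     **overrides) -> SimulationConfig:
    """Null configuration: constant weights (mental > physical) in both groups."""
    cfg = SimulationConfig(
        n_worsened=n_worsened, n_not_worsened=n_not_worsened,
        weight_curves={WORSENED: _constant_weights(contrast),
                       NOT_WORSENED: _constant_weights(contrast)},
        seed=seed, scenario="control", crossing_time=None, **overrides)
    cfg.validate()
    return cfg


def reprioritization_scenario(crossing_time: float = 2.0,
                              strength: float = 0.5,
                              n_worsened: int = 107,
                              n_not_worsened: int = 417,
                              control_contrast: float = 0.3,
                              seed: int = 0, **overrides) -> SimulationConfig:
    """Reprioritization in the worsened group only.

    The worsened group's mental/physical cluster weight contrast declines
    linearly from ``control_contrast + strength`` at M0 through zero exactly
    at ``crossing_time`` (mental and physical weights intersect there); the
    control group keeps the constant contrast.  ``strength = 0`` means no
    reprioritization and returns the control configuration.
    """
    if strength == 0:
        return control_scenario(n_worsened, n_not_worsened,
                                contrast=control_contrast, seed=seed,
                                **overrides)
    if not 0 < crossing_time < 4:
        raise SimulationError("crossing_time must lie in (0, 4)")
    t = np.arange(N_VISITS, dtype=float)
    contrast = (control_contrast + strength) * (1.0 - t / crossing_time)
    worsened = {}
    for d in MENTAL_DOMAINS:
        worsened[d] = np.clip(1.0 + contrast, 0.0, None)
    for d in PHYSICAL_DOMAINS:
        worsened[d] = np.clip(1.0 - contrast, 0.0, None)
    cfg = SimulationConfig(
        n_worsened=n_worsened, n_not_worsened=n_not_worsened,
        weight_curves={WORSENED: worsened,
                       NOT_WORSENED: _constant_weights(control_contrast)},
        seed=seed, scenario="reprioritization",
        crossing_time=float(crossing_time), **overrides)
    cfg.validate()
    return cfg


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _round_half(x):
    return np.round(np.asarray(x) * 2.0) / 2.0


def _draw_edss_trajectories(rng, groups, cfg):
    """Baseline + per-visit EDSS such that the classifier reproduces groups.

    Worsened patients gain the group's clinically meaningful increment
    (1.0 below baseline 5.5, 0.5 at or above) plus occasional extra steps;
    not-worsened patients stay flat, dip half a point, or rise just below
    the worsening threshold.  Infeasible draws (progression would exceed
    the 0-10 grid) trigger a bounded baseline resample.
    """
    n = len(groups)
    worsened = groups == WORSENED
    base = np.empty(n)
    delta = np.empty(n)
    for attempt in range(100):
        todo = (np.ones(n, bool) if attempt == 0
                else np.array([classify_disability_change(base[i],
                                                          base[i] + delta[i])
                               != groups[i] for i in range(n)]))
        m = int(todo.sum())
        if m == 0:
            break
        b = _round_half(_truncated_normal(rng, cfg.edss_mean, cfg.edss_sd,
                                          0.0, cfg.edss_max, m))
        need = np.where(b < 5.5, 1.0, 0.5)
        u = rng.random(m)
        w = worsened[todo]
        extra = np.where(u < 0.6, 0.0, np.where(u < 0.9, 0.5, 1.0))
        d_w = np.minimum(need + extra, _round_half(10.0 - b))
        d_nw = np.where(u < 0.25, -0.5, np.where(u < 0.80, 0.0, need - 0.5))
        d_nw = np.where(b + d_nw < 0.0, 0.0, d_nw)
        d = np.where(w, d_w, d_nw)
        base[todo] = b
        delta[todo] = d
    else:
        raise SimulationError("could not draw feasible EDSS trajectories")
    t = np.arange(N_VISITS) / (N_VISITS - 1)
    traj = _round_half(base[:, None] + delta[:, None] * t[None, :])
    traj = np.clip(traj, 0.0, 10.0)
    traj[:, 0] = base
    traj[:, -1] = base + delta
    return traj


def _draw_covariates(rng, n, cfg):
    age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, 18.0, np.inf, n)
    gender = np.where(rng.random(n) < cfg.p_female, "female", "male")
    edu_levels = np.array(["elementary", "college", "high_school_university"])
    probs = np.asarray(cfg.education_probs, float)
    education = rng.choice(edu_levels, size=n, p=probs / probs.sum())
    marital = np.where(rng.random(n) < cfg.p_cohabiting,
                       "cohabiting_married", "other")
    employment = np.where(rng.random(n) < cfg.p_employed, "employed", "other")
    duration = _truncated_normal(rng, cfg.duration_mean, cfg.duration_sd,
                                 0.0, np.inf, n)
    return pd.DataFrame({
        "age": np.round(age, 1), "gender": gender, "education": education,
        "marital": marital, "employment": employment,
        "disease_duration": np.round(duration, 1)})


def _musiqol_dimensions(rng, index):
    """Nine dimension scores whose mean equals the index exactly.

    Deviations are drawn, centered, and shrunk per row just enough to keep
    every dimension inside [0, 100] without disturbing the mean.
    """
    n = len(index)
    dev = rng.normal(0.0, 8.0, size=(n, len(MUSIQOL_DIMENSIONS)))
    dev -= dev.mean(axis=1, keepdims=True)
    lo = np.min(dev, axis=1)
    hi = np.max(dev, axis=1)
    shrink = np.ones(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        cap_hi = np.where(hi > 0, (100.0 - index) / hi, np.inf)
        cap_lo = np.where(lo < 0, (0.0 - index) / lo, np.inf)
    shrink = np.minimum(1.0, np.minimum(cap_hi, cap_lo))
    return index[:, None] + shrink[:, None] * dev


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Generate a labeled longitudinal cohort under the configured scenario.

    Deterministic given ``config.seed``; applying the disability-change
    classifier to the emitted EDSS trajectories reproduces the intended
    group of every patient.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_worsened + config.n_not_worsened
    groups = np.array([WORSENED] * config.n_worsened
                      + [NOT_WORSENED] * config.n_not_worsened)
    pids = np.array([f"P{i + 1:05d}" for i in range(n)])

    cov = _draw_covariates(rng, n, config)
    edss = _draw_edss_trajectories(rng, groups, config)

    # latent domain process: MVN innovations with AR(1) persistence
    chol = np.linalg.cholesky(
        config.domain_corr + 1e-12 * np.eye(len(DOMAINS)))
    z = np.empty((n, N_VISITS, len(DOMAINS)))
    eps = rng.standard_normal((n, len(DOMAINS))) @ chol.T
    z[:, 0, :] = eps
    rho = config.ar1_rho
    for t in range(1, N_VISITS):
        eps = rng.standard_normal((n, len(DOMAINS))) @ chol.T
        z[:, t, :] = rho * z[:, t - 1, :] + np.sqrt(1 - rho ** 2) * eps

    # observed 0-100 domain scores, depressed by current disability
    effect = np.array([config.edss_physical_effect if d in PHYSICAL_DOMAINS
                       else config.edss_mental_effect for d in DOMAINS])
    scores = (config.domain_base + config.domain_scale * z
              - effect[None, None, :] * edss[:, :, None])
    scores = np.clip(scores, 0.0, 100.0)

    # baseline-sample norms: domain standardization and T-score composites
    mu = scores[:, 0, :].mean(axis=0)
    sd = scores[:, 0, :].std(axis=0)
    if (sd == 0).any():
        raise SimulationError("degenerate domain scores at baseline")
    zstd = (scores - mu[None, None, :]) / sd[None, None, :]

    phys_idx = [DOMAINS.index(d) for d in PHYSICAL_DOMAINS]
    ment_idx = [DOMAINS.index(d) for d in MENTAL_DOMAINS]
    comps = {}
    for name, idx in (("pcs", phys_idx), ("mcs", ment_idx)):
        avg = zstd[:, :, idx].mean(axis=2)
        m0, s0 = avg[:, 0].mean(), avg[:, 0].std()
        comps[name] = config.tscore_mean + config.tscore_sd * (avg - m0) / s0

    # global index from normalized time-varying weights + residual noise
    weights = np.empty((n, N_VISITS, len(DOMAINS)))
    for g in (WORSENED, NOT_WORSENED):
        mask = groups == g
        w = np.stack([np.asarray(config.weight_curves[g][d], float)
                      for d in DOMAINS], axis=1)  # (visits, domains)
        w = w / w.sum(axis=1, keepdims=True)
        weights[mask] = w[None, :, :]
    u = (weights * zstd).sum(axis=2)
    index = (50.0 + config.index_gain * u
             + rng.normal(0.0, config.noise_sd, size=(n, N_VISITS)))
    index = np.clip(index, 0.0, 100.0)

    records = []
    for t in range(N_VISITS):
        block = pd.DataFrame({
            "patient_id": pids, "month": 6 * t, "edss": edss[:, t]})
        for j, d in enumerate(DOMAINS):
            block[d] = np.round(scores[:, t, j], 2)
        block["pcs"] = np.round(comps["pcs"][:, t], 2)
        block["mcs"] = np.round(comps["mcs"][:, t], 2)
        block["musiqol_index"] = np.round(index[:, t], 2)
        for c in cov.columns:
            block[c] = cov[c].to_numpy()
        if config.emit_dimensions:
            dims = _musiqol_dimensions(
                np.random.default_rng((config.seed, 1000 + t)),
                block["musiqol_index"].to_numpy(float))
            for j, name in enumerate(MUSIQOL_DIMENSIONS):
                block[f"dim_{name}"] = dims[:, j]
        records.append(block)
    df = pd.concat(records, ignore_index=True)

    if config.missing_rate > 0:
        qol_cols = list(DOMAINS) + ["pcs", "mcs", "musiqol_index"]
        mask = rng.random((len(df), len(qol_cols))) < config.missing_rate
        for j, c in enumerate(qol_cols):
            df.loc[mask[:, j], c] = np.nan

    labels = dict(zip(pids, groups))
    # construction guarantee: the classifier must reproduce intended labels
    for i in range(n):
        got = classify_disability_change(edss[i, 0], edss[i, -1])
        if got != groups[i]:
            raise SimulationError(
                f"internal error: intended {groups[i]} but classified {got} "
                f"for {pids[i]}")
    return CohortTable(data=df, group_labels=labels)
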