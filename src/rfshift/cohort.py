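"""Longitudinal cohort tables: I/O, disability-change grouping, designs, matching.

The cohort is a long-format table, one row per patient-visit, carrying the
EDSS, the eight SF-36 scale scores, the PCS/MCS composites, the MusiQoL
global index, and baseline covariates.  Visits are every six months from
inclusion: M0, M6, M12, M18, M24, encoded internally as t = month / 6.

Disability change at 24 months follows the neurological standard: a patient
worsened if the EDSS increased by >= 1.0 point from a baseline below 5.5, or
by >= 0.5 point from a baseline of 5.5 or more; all other classifiable
patients are not-worsened.  Patients missing the baseline or 24-month EDSS
are unclassifiable and excluded downstream.  The not-worsened group serves
as the control arm for response-shift detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .errors import (CohortFormatError, CohortIntegrityError,
                     EmptyDesignError, MatchingError)
from .models import ModelSpec

__all__ = ["CohortTable", "read_cohort", "write_cohort",
           "write_group_labels", "classify_disability_change",
           "label_groups", "match_on_baseline_edss", "build_design_matrix",
           "WORSENED", "NOT_WORSENED", "COLUMNS", "COVARIATE_LEVELS"]

WORSENED = "worsened"
NOT_WORSENED = "not_worsened"
GROUPS = (WORSENED, NOT_WORSENED)

MONTHS = (0, 6, 12, 18, 24)
SCALE_COLUMNS = ("pf", "rp", "vitality", "bp", "sf", "re", "mh", "gh")
SCORE_COLUMNS = SCALE_COLUMNS + ("musiqol_index",)
COLUMNS = ("patient_id", "month", "edss") + SCALE_COLUMNS + (
    "pcs", "mcs", "musiqol_index", "age", "gender", "education", "marital",
    "employment", "disease_duration")

# fixed category levels; the first level of each is the one-hot reference
COVARIATE_LEVELS = {
    "gender": ("female", "male"),
    "education": ("elementary", "college", "high_school_university"),
    "marital": ("cohabiting_married", "other"),
    "employment": ("employed", "other"),
}
NUMERIC_COVARIATES = ("age", "disease_duration")


def _encoded_covariate_names() -> list[str]:
    names = list(NUMERIC_COVARIATES)
    for var, levels in COVARIATE_LEVELS.items():
        names += [f"{var}_{lev}" for lev in levels[1:]]
    return names


@dataclass
class CohortTable:
    """Validated long-format cohort plus optional patient group labels."""

    data: pd.DataFrame
    group_labels: dict | None = None
    unclassified: list = field(default_factory=list)

    def __post_init__(self):
        if "visit" not in self.data.columns:
            self.data = self.data.assign(visit=self.data["month"] // 6)

    @property
    def patients(self) -> list:
        return list(pd.unique(self.data["patient_id"]))

    @property
    def n_records(self) -> int:
        return len(self.data)

    def patients_in_group(self, group: str) -> list:
        if self.group_labels is None:
            raise MatchingError("cohort has no group labels")
        return [p for p, g in self.group_labels.items() if g == group]

    def baseline_edss(self) -> pd.Series:
        base = self.data[self.data["visit"] == 0]
        return base.set_index("patient_id")["edss"]


def _validate(df: pd.DataFrame) -> list[str]:
    problems = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        month = row["month"]
        if month not in MONTHS:
            problems.append(f"row {rowno}: month {month!r} not in {MONTHS}")
        edss = row["edss"]
        if not pd.isna(edss):
            if not (0 <= edss <= 10) or abs(edss * 2 - round(edss * 2)) > 1e-9:
                problems.append(
                    f"row {rowno}: edss {edss} not on the 0-10 half-point grid")
        for col in SCORE_COLUMNS:
            v = row[col]
            if not pd.isna(v) and not 0 <= v <= 100:
                problems.append(f"row {rowno}: {col} {v} outside [0, 100]")
        if not pd.isna(row["age"]) and row["age"] < 18:
            problems.append(f"row {rowno}: age {row['age']} below 18")
        if not pd.isna(row["disease_duration"]) and row["disease_duration"] < 0:
            problems.append(f"row {rowno}: negative disease_duration")
        for var, levels in COVARIATE_LEVELS.items():
            v = row[var]
            if not pd.isna(v) and v not in levels:
                problems.append(
                    f"row {rowno}: {var} {v!r} not one of {levels}")
    dup = df.duplicated(subset=["patient_id", "month"])
    for i in df.index[dup]:
        problems.append(
            f"row {i + 2}: duplicate (patient_id, month) = "
            f"({df.loc[i, 'patient_id']!r}, {df.loc[i, 'month']})")
    return problems


def read_cohort(path) -> CohortTable:
    """Read and validate a long-format cohort CSV.

    Raises CohortFormatError for missing columns and CohortIntegrityError
    (with row-level diagnostics) for range/grid violations and duplicate
    (patient_id, month) pairs.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing mandatory column(s): {missing}")
    df = df[list(COLUMNS)]
    numeric = [c for c in COLUMNS
               if c not in ("patient_id",) + tuple(COVARIATE_LEVELS)]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="raise")
    df["month"] = df["month"].astype(int)
    problems = _validate(df)
    if problems:
        raise CohortIntegrityError("; ".join(problems[:20]) + (
            f" (+{len(problems) - 20} more)" if len(problems) > 20 else ""))
    return CohortTable(data=df.reset_index(drop=True))


def write_cohort(table: CohortTable, path) -> None:
    """Write the cohort back to CSV (month column, empty fields for NaN)."""
    table.data[list(COLUMNS)].to_csv(path, index=False)


def write_group_labels(table: CohortTable, path) -> None:
    """Write the patient_id -> group map as a two-column CSV."""
    if table.group_labels is None:
        raise MatchingError("cohort has no group labels to write")
    pd.DataFrame(
        {"patient_id": list(table.group_labels),
         "group": list(table.group_labels.values())},
    ).to_csv(path, index=False)


def classify_disability_change(edss_baseline, edss_m24):
    """Disability-change group from baseline and 24-month EDSS.

    Worsened iff the increase reaches 1.0 point for baselines below 5.5, or
    0.5 point for baselines of 5.5 and above (the half-point rule is also
    applied above 7.0).  Returns None when either score is missing
    (unclassifiable patient).
    """
    if edss_baseline is None or edss_m24 is None:
        return None
    if np.isnan(edss_baseline) or np.isnan(edss_m24):
        return None
    delta = edss_m24 - edss_baseline
    threshold = 1.0 if edss_baseline < 5.5 else 0.5
    return WORSENED if delta >= threshold - 1e-9 else NOT_WORSENED


def label_groups(cohort: CohortTable) -> CohortTable:
    """Derive disability-change labels from the cohort's EDSS trajectory.

    Patients without both a baseline and a 24-month EDSS are recorded in
    ``unclassified`` and carry no label.
    """
    df = cohort.data
    base = df[df["visit"] == 0].set_index("patient_id")["edss"]
    m24 = df[df["visit"] == 4].set_index("patient_id")["edss"]
    labels, unclassified = {}, []
    for pid in pd.unique(df["patient_id"]):
        g = classify_disability_change(base.get(pid, np.nan),
                                       m24.get(pid, np.nan))
        if g is None:
            unclassified.append(pid)
        else:
            labels[pid] = g
    return CohortTable(data=df, group_labels=labels,
                       unclassified=unclassified)


def match_on_baseline_edss(cohort: CohortTable, n_per_group: int,
                           seed: int) -> CohortTable:
    """1:1 greedy nearest-neighbour matching on baseline EDSS.

    Draws ``n_per_group`` worsened patients in seed-randomized order and
    pairs each, without replacement, with the closest not-worsened patient
    by absolute baseline-EDSS distance (ties broken by the seed-determined
    control order).  Returns the matched sub-cohort; the pairing is stored
    on the result as ``matched_pairs``.
    """
    if cohort.group_labels is None:
        raise MatchingError("cohort must be labeled before matching")
    base = cohort.baseline_edss()
    rng = np.random.default_rng(seed)

    def _candidates(group):
        pids = [p for p in cohort.patients_in_group(group)
                if p in base.index and not pd.isna(base[p])]
        return [pids[i] for i in rng.permutation(len(pids))]

    worsened = _candidates(WORSENED)
    controls = _candidates(NOT_WORSENED)
    if len(worsened) < n_per_group or len(controls) < n_per_group:
        raise MatchingError(
            f"need {n_per_group} per group; available worsened="
            f"{len(worsened)}, not_worsened={len(controls)}")
    pairs = []
    available = list(controls)
    for pid in worsened[:n_per_group]:
        dists = [abs(base[pid] - base[c]) for c in available]
        j = int(np.argmin(dists))  # first minimum in seed-shuffled order
        pairs.append((pid, available.pop(j)))
    keep = {p for pair in pairs for p in pair}
    sub = cohort.data[cohort.data["patient_id"].isin(keep)]
    out = CohortTable(data=sub.reset_index(drop=True),
                      group_labels={p: cohort.group_labels[p] for p in keep})
    out.matched_pairs = pairs
    return out


def build_design_matrix(cohort: CohortTable, visit: int, group: str,
                        model_spec: ModelSpec) -> DesignMatrix:
    """Complete-case design for one (visit, group, model) regression.

    y is the MusiQoL global index at the visit; predictors are the model's
    QoL scores followed by the encoded covariates (fixed reference levels,
    stable column order across visits).  Rows with any missing required
    value are dropped; zero remaining rows raises EmptyDesignError.
    """
    if visit not in range(5):
        raise ValueError("visit must be in 0..4")
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if cohort.group_labels is None:
        raise MatchingError("cohort must be labeled; call label_groups first")
    pids = set(cohort.patients_in_group(group))
    df = cohort.data
    rows = df[(df["visit"] == visit) & (df["patient_id"].isin(pids))]
    qol = list(model_spec.qol_predictors)
    needed = qol + ["musiqol_index"]
    if model_spec.include_covariates:
        needed += list(NUMERIC_COVARIATES) + list(COVARIATE_LEVELS)
    rows = rows.dropna(subset=needed)
    if len(rows) == 0:
        raise EmptyDesignError(
            f"no complete cases at visit {visit} for group {group!r}")
    blocks = [rows[qol].to_numpy(float)]
    names = list(qol)
    column_groups = {c: [c] for c in qol}
    if model_spec.include_covariates:
        blocks.append(rows[list(NUMERIC_COVARIATES)].to_numpy(float))
        names += list(NUMERIC_COVARIATES)
        column_groups.update({c: [c] for c in NUMERIC_COVARIATES})
        for var, levels in COVARIATE_LEVELS.items():
            members = []
            for lev in levels[1:]:
                col = f"{var}_{lev}"
                blocks.append(
                    (rows[var] == lev).to_numpy(float)[:, None])
                names.append(col)
                members.append(col)
            column_groups[var] = members
    X = np.hstack([b if b.ndim == 2 else b[:, None] for b in blocks])
    return DesignMatrix(
        predictor_names=names, X=X,
        y=rows["musiqol_index"].to_numpy(float), model_spec=model_spec,
        visit=visit, group=group, column_groups=column_groups,
        patient_ids=list(rows["patient_id"]))
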