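import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfshift import cohort as ch
from rfshift.errors import (CohortFormatError, CohortIntegrityError,
                            EmptyDesignError, MatchingError)
from rfshift.models import M1, M2, ModelSpec

from conftest import make_cohort_frame, make_visit_row

edss_grid = st.integers(0, 20).map(lambda k: k / 2.0)


class TestReadWrite:
    def test_reads_valid_fixture(self, tiny_cohort_csv):
        table = ch.read_cohort(tiny_cohort_csv)
        assert table.n_records == 3
        assert set(table.patients) == {"P1", "P2"}
        assert list(table.data["visit"][:2]) == [0, 1]

    def test_off_grid_edss_rejected_with_row_number(self, tmp_path):
        df = make_cohort_frame([make_visit_row("P1", 0, edss=3.2)])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortIntegrityError, match="row 2.*3.2"):
            ch.read_cohort(path)

    def test_score_out_of_range_rejected(self, tmp_path):
        df = make_cohort_frame([make_visit_row("P1", 0, pf=101.0)])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortIntegrityError, match="pf"):
            ch.read_cohort(path)

    def test_missing_column_is_format_error(self, tmp_path):
        df = make_cohort_frame([make_visit_row()]).drop(columns=["mcs"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortFormatError, match="mcs"):
            ch.read_cohort(path)

    def test_duplicate_patient_visit_rejected(self, tmp_path):
        df = make_cohort_frame([make_visit_row("P1", 0),
                                make_visit_row("P1", 0)])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortIntegrityError, match="duplicate"):
            ch.read_cohort(path)

    def test_round_trip_preserves_table(self, tiny_cohort_csv, tmp_path):
        t1 = ch.read_cohort(tiny_cohort_csv)
        out = tmp_path / "copy.csv"
        ch.write_cohort(t1, out)
        t2 = ch.read_cohort(out)
        pd.testing.assert_frame_equal(t1.data, t2.data)


class TestClassify:
    @pytest.mark.parametrize("baseline,m24,expected", [
        (4.0, 5.0, ch.WORSENED),       # one-point rule below 5.5
        (6.0, 6.5, ch.WORSENED),       # half-point rule at/above 5.5
        (4.0, 4.5, ch.NOT_WORSENED),   # increase below threshold
        (3.0, 3.0, ch.NOT_WORSENED),   # no change
        (5.5, 6.0, ch.WORSENED),       # boundary baseline uses half-point rule
        (5.0, 5.5, ch.NOT_WORSENED),   # just below the boundary, needs 1.0
        (7.5, 8.0, ch.WORSENED),       # above 7.0: half-point rule extended
        (2.0, 1.0, ch.NOT_WORSENED),   # improvement
    ])
    def test_rule(self, baseline, m24, expected):
        assert ch.classify_disability_change(baseline, m24) == expected

    def test_missing_score_is_unclassifiable(self):
        assert ch.classify_disability_change(np.nan, 4.0) is None
        assert ch.classify_disability_change(3.0, None) is None

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(edss_grid, edss_grid, edss_grid)
    def test_monotone_in_follow_up_and_partition(self, b, m, m2):
        g = ch.classify_disability_change(b, m)
        assert g in (ch.WORSENED, ch.NOT_WORSENED)  # partition
        if g == ch.WORSENED and m2 >= m:
            assert ch.classify_disability_change(b, m2) == ch.WORSENED


def _labeled_cohort(baselines_w, baselines_nw):
    rows = []
    labels = {}
    for i, b in enumerate(baselines_w):
        pid = f"W{i}"
        rows += [make_visit_row(pid, 0, edss=b),
                 make_visit_row(pid, 24, edss=min(b + 1.0, 10.0))]
        labels[pid] = ch.WORSENED
    for i, b in enumerate(baselines_nw):
        pid = f"N{i}"
        rows += [make_visit_row(pid, 0, edss=b),
                 make_visit_row(pid, 24, edss=b)]
        labels[pid] = ch.NOT_WORSENED
    return ch.CohortTable(data=make_cohort_frame(rows), group_labels=labels)


def optimal_assignment_cost(worsened, controls, n):
    """Oracle: minimum total |EDSS difference| over all 1:1 assignments."""
    best = np.inf
    for subset_w in itertools.combinations(worsened, n):
        for subset_c in itertools.permutations(controls, n):
            cost = sum(abs(a - b) for a, b in zip(subset_w, subset_c))
            best = min(best, cost)
    return best


class TestMatching:
    def test_perfect_overlap_gives_zero_distances(self):
        table = _labeled_cohort([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        matched = ch.match_on_baseline_edss(table, 3, seed=0)
        base = matched.baseline_edss()
        for w, c in matched.matched_pairs:
            assert base[w] == base[c]

    def test_small_instance_reaches_optimal_assignment(self):
        table = _labeled_cohort([2.0, 6.0], [2.5, 5.5, 0.0])
        matched = ch.match_on_baseline_edss(table, 2, seed=1)
        pairs = {(w, c) for w, c in matched.matched_pairs}
        base = table.baseline_edss()
        cost = sum(abs(base[w] - base[c]) for w, c in pairs)
        assert cost == pytest.approx(
            optimal_assignment_cost([2.0, 6.0], [2.5, 5.5, 0.0], 2))
        pair_edss = {(base[w], base[c]) for w, c in pairs}
        assert pair_edss == {(2.0, 2.5), (6.0, 5.5)}

    def test_same_seed_is_deterministic(self):
        table = _labeled_cohort([1.0, 2.0, 3.5, 4.0], [1.5, 2.0, 3.0, 5.0])
        m1 = ch.match_on_baseline_edss(table, 3, seed=7)
        m2 = ch.match_on_baseline_edss(table, 3, seed=7)
        assert m1.matched_pairs == m2.matched_pairs

    def test_insufficient_patients_reports_counts(self):
        table = _labeled_cohort([1.0], [2.0, 3.0])
        with pytest.raises(MatchingError, match="worsened=1"):
            ch.match_on_baseline_edss(table, 2, seed=0)

    def test_unlabeled_cohort_rejected(self):
        table = ch.CohortTable(data=make_cohort_frame([make_visit_row()]))
        with pytest.raises(MatchingError):
            ch.match_on_baseline_edss(table, 1, seed=0)


class TestLabelGroups:
    def test_labels_and_unclassified(self):
        rows = [
            make_visit_row("A", 0, edss=2.0), make_visit_row("A", 24, edss=3.0),
            make_visit_row("B", 0, edss=2.0), make_visit_row("B", 24, edss=2.0),
            make_visit_row("C", 0, edss=2.0),  # no 24-month EDSS
        ]
        table = ch.label_groups(ch.CohortTable(data=make_cohort_frame(rows)))
        assert table.group_labels == {"A": ch.WORSENED, "B": ch.NOT_WORSENED}
        assert table.unclassified == ["C"]


class TestDesignMatrix:
    def _table(self):
        rows = []
        for pid, mcs1 in (("A", 52.0), ("B", None), ("C", 48.0)):
            rows.append(make_visit_row(pid, 0, edss=2.0))
            rows.append(make_visit_row(pid, 6, edss=2.0, mcs=mcs1))
            rows.append(make_visit_row(pid, 24, edss=3.0))
        labels = {p: ch.WORSENED for p in "ABC"}
        return ch.CohortTable(data=make_cohort_frame(rows),
                              group_labels=labels)

    def test_m1_column_order(self):
        d = ch.build_design_matrix(self._table(), 0, ch.WORSENED, M1)
        assert d.predictor_names[:2] == ["pcs", "mcs"]
        assert d.predictor_names[2:4] == ["age", "disease_duration"]
        assert "gender_male" in d.predictor_names
        assert d.column_groups["education"] == [
            "education_college", "education_high_school_university"]

    def test_m2_column_order(self):
        d = ch.build_design_matrix(self._table(), 0, ch.WORSENED, M2)
        assert d.predictor_names[:8] == list(M2.qol_predictors)

    def test_complete_case_drops_row_only_at_affected_visit(self):
        table = self._table()
        d0 = ch.build_design_matrix(table, 0, ch.WORSENED, M1)
        d1 = ch.build_design_matrix(table, 1, ch.WORSENED, M1)
        assert d0.n == 3
        assert d1.n == 2
        assert "B" not in d1.patient_ids

    def test_empty_design_raises(self):
        table = self._table()
        with pytest.raises(EmptyDesignError):
            ch.build_design_matrix(table, 2, ch.WORSENED, M1)

    def test_no_covariates_spec(self):
        spec = ModelSpec("M1", ("pcs", "mcs"), include_covariates=False)
        d = ch.build_design_matrix(self._table(), 0, ch.WORSENED, spec)
        assert d.predictor_names == ["pcs", "mcs"]
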