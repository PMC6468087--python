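"""Fidelity indices, robust standardization, Ward clustering, comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fincr.fidelity import (
    EffortLog,
    cut_two_groups,
    fidelity_indices,
    group_comparisons,
    robust_standardize,
    ward_linkage,
)


def _records(entries):
    rows = [(i, d, "JCP", False, "U") for i, d in entries]
    return pd.DataFrame(
        rows, columns=["individual_id", "date", "area", "calf", "sex"]
    )


class TestFidelityIndices:
    def test_annual_rate_definition(self):
        recs = _records(
            [("A", "2010-06-01"), ("A", "2012-06-01"), ("A", "2014-06-01")]
        )
        effort = EffortLog({y: 50 for y in range(2010, 2017)})
        idx = fidelity_indices(recs, effort, last_year=2016,
                               min_tenure_cutoff_year=2011)
        assert idx.loc["A", "annual_rate"] == pytest.approx(3 / 7)

    def test_rate_one_when_seen_every_year(self):
        recs = _records([("A", f"{y}-06-01") for y in range(2010, 2017)])
        effort = EffortLog({y: 50 for y in range(2010, 2017)})
        idx = fidelity_indices(recs, effort, last_year=2016)
        assert idx.loc["A", "annual_rate"] == 1.0

    def test_survey_rate_definition(self):
        recs = _records(
            [("A", f"2015-06-{d:02d}") for d in (1, 3, 5, 7, 9)]
            + [("B", "2010-06-01")]
        )
        effort = EffortLog({y: 25 for y in range(2010, 2017)})
        idx = fidelity_indices(recs, effort, last_year=2016,
                               min_tenure_cutoff_year=2015)
        # first seen 2015: 25 + 25 survey days remain, 5 days seen
        assert idx.loc["A", "survey_rate"] == pytest.approx(5 / 50)

    def test_late_first_sighting_excluded(self):
        recs = _records([("A", "2010-06-01"), ("B", "2015-06-01")])
        effort = EffortLog({y: 50 for y in range(2010, 2017)})
        idx = fidelity_indices(recs, effort, last_year=2016,
                               min_tenure_cutoff_year=2011)
        assert "B" not in idx.index


class TestRobustStandardize:
    def test_hand_arithmetic(self):
        out = robust_standardize([1, 2, 3, 4, 100])
        assert out.tolist() == [-2, -1, 0, 1, 97]

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="deviation"):
            robust_standardize([5.0] * 10)

    @given(st.lists(st.floats(-100, 100), min_size=10, max_size=100))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_output_has_median_zero_mad_one(self, values):
        v = np.asarray(values)
        med = np.median(v)
        if np.median(np.abs(v - med)) == 0:
            return
        out = robust_standardize(v)
        assert np.median(out) == pytest.approx(0, abs=1e-9)
        assert np.median(np.abs(out - np.median(out))) == pytest.approx(1, abs=1e-9)


def _ward_oracle_merges(pts):
    """Exhaustive Ward agglomeration: merge the pair with the smallest
    increase in total within-cluster sum of squares at every step."""
    clusters = [frozenset([i]) for i in range(len(pts))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                A, B = list(clusters[i]), list(clusters[j])
                cA, cB = pts[A].mean(axis=0), pts[B].mean(axis=0)
                d = len(A) * len(B) / (len(A) + len(B)) * ((cA - cB) ** 2).sum()
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def _merges_from_linkage(Z, n):
    sets = {i: frozenset([i]) for i in range(n)}
    merges = []
    for k, (a, b, _, _) in enumerate(Z):
        merged = sets[int(a)] | sets[int(b)]
        sets[n + k] = merged
        merges.append(merged)
    return merges


class TestWardLinkage:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_ward_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        pts = rng.normal(size=(n, 2))
        Z = ward_linkage(pts)
        assert _merges_from_linkage(Z, n) == _ward_oracle_merges(pts)

    @pytest.mark.parametrize("variant", ["ward", "ward_d"])
    def test_heights_nondecreasing(self, variant):
        pts = np.random.default_rng(7).normal(size=(30, 2))
        Z = ward_linkage(pts, variant=variant)
        assert (np.diff(Z[:, 2]) >= -1e-9).all()

    def test_two_tight_pairs_merge_first(self):
        pts = np.array([[0, 0], [0.01, 0], [5, 5], [5.01, 5]])
        Z = ward_linkage(pts)
        first_two = {frozenset(map(int, Z[0, :2])), frozenset(map(int, Z[1, :2]))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}


class TestCutTwoGroups:
    @staticmethod
    def _mixture(seed=0, n=200):
        rng = np.random.default_rng(seed)
        n_hi = n // 4
        hi = np.column_stack(
            [rng.uniform(0.7, 1.0, n_hi), rng.uniform(0.10, 0.2, n_hi)]
        )
        lo = np.column_stack(
            [rng.uniform(0.02, 0.25, n - n_hi), rng.uniform(0.001, 0.02, n - n_hi)]
        )
        pts = np.vstack([hi, lo])
        idx = pd.DataFrame(
            pts,
            columns=["annual_rate", "survey_rate"],
            index=[f"i{k}" for k in range(n)],
        )
        labels_true = np.array(["hi"] * n_hi + ["lo"] * (n - n_hi))
        return idx, labels_true

    def test_recovers_well_separated_mixture(self):
        idx, truth = self._mixture()
        pts = np.column_stack(
            [robust_standardize(idx["annual_rate"]), robust_standardize(idx["survey_rate"])]
        )
        res = cut_two_groups(ward_linkage(pts), idx)
        agree = ((res.labels == "core_regular") == (truth == "hi")).mean()
        assert agree >= 0.95
        assert res.group_summaries["n"].sum() == len(idx)
        # higher mean annual rate group carries the core label
        ms = idx.groupby(res.labels)["annual_rate"].mean()
        assert ms["core_regular"] > ms["occasional_visitor"]

    def test_base_case_two_points(self):
        idx = pd.DataFrame(
            {"annual_rate": [0.1, 0.9], "survey_rate": [0.01, 0.2]},
            index=["a", "b"],
        )
        res = cut_two_groups(ward_linkage(idx.to_numpy()), idx)
        assert set(res.group_summaries["n"]) == {1}

    def test_invariant_to_input_order(self):
        idx, _ = self._mixture(seed=5)
        pts = np.column_stack(
            [robust_standardize(idx["annual_rate"]), robust_standardize(idx["survey_rate"])]
        )
        res1 = cut_two_groups(ward_linkage(pts), idx)
        perm = np.random.default_rng(1).permutation(len(idx))
        res2 = cut_two_groups(ward_linkage(pts[perm]), idx.iloc[perm])
        assert res1.labels.sort_index().equals(res2.labels.sort_index())


class TestGroupComparisons:
    def test_welch_t_matches_direct_formula(self):
        a = np.array([0.8, 0.9, 0.85, 0.95, 0.7])
        b = np.array([0.2, 0.1, 0.3, 0.25])
        idx = pd.DataFrame(
            {
                "annual_rate": np.r_[a, b],
                "survey_rate": np.r_[a, b] / 10,
            },
            index=[f"i{k}" for k in range(9)],
        )
        labels = pd.Series(["x"] * 5 + ["y"] * 4, index=idx.index)
        out = group_comparisons(labels, idx)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t = (a.mean() - b.mean()) / np.sqrt(va / 5 + vb / 4)
        df = (va / 5 + vb / 4) ** 2 / (
            (va / 5) ** 2 / 4 + (vb / 4) ** 2 / 3
        )
        assert out["annual_rate"]["t"] == pytest.approx(t)
        assert out["annual_rate"]["df"] == pytest.approx(df)

    def test_identical_groups_give_t_zero(self):
        block = np.array([0.1, 0.5, 0.9])
        idx = pd.DataFrame(
            {"annual_rate": np.r_[block, block], "survey_rate": np.r_[block, block]},
            index=[f"i{k}" for k in range(6)],
        )
        labels = pd.Series(["x"] * 3 + ["y"] * 3, index=idx.index)
        out = group_comparisons(labels, idx)
        assert out["annual_rate"]["t"] == pytest.approx(0.0)

    def test_sex_ratio_chi_square_on_study_counts(self):
        """2-sample equality of proportions with Yates correction:
        31 F / 63 M in one group against 37 F / 58 M in the other."""
        labels = pd.Series(
            ["core"] * 94 + ["occ"] * 95,
            index=[f"i{k}" for k in range(189)],
        )
        sex = pd.Series(
            ["F"] * 31 + ["M"] * 63 + ["F"] * 37 + ["M"] * 58, index=labels.index
        )
        idx = pd.DataFrame(
            {
                "annual_rate": np.random.default_rng(0).uniform(0.1, 0.9, 189),
                "survey_rate": np.random.default_rng(1).uniform(0.01, 0.2, 189),
            },
            index=labels.index,
        )
        out = group_comparisons(labels, idx, sex)
        assert out["sex_ratio"]["chi2"] == pytest.approx(0.49, abs=0.005)
        assert out["sex_ratio"]["df"] == 1
        assert out["sex_ratio"]["p"] == pytest.approx(0.48, abs=0.005)
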