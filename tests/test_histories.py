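"""Sighting parsing, capture-history construction, and covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fincr.histories import (
    CaptureHistorySet,
    area_exchange_summary,
    build_histories,
    read_sightings,
    sexed_subset,
    transient_covariates,
    trap_covariates,
    truncate,
    write_sightings,
)
from fincr.simulate import scenario_presets, simulate


def _write(df, tmp_path, name="s.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


class TestReadSightings:
    def test_identity_parse(self, tiny_records, tmp_path):
        recs = read_sightings(_write(tiny_records, tmp_path))
        assert len(recs) == 6
        assert list(recs["individual_id"][:3]) == ["A", "A", "A"]

    def test_duplicate_collapse(self, tiny_records, tmp_path):
        doubled = pd.concat([tiny_records, tiny_records.iloc[[0]]])
        recs = read_sightings(_write(doubled, tmp_path))
        assert len(recs) == 6

    def test_missing_column_is_format_error(self, tiny_records, tmp_path):
        with pytest.raises(ValueError, match="date"):
            read_sightings(_write(tiny_records.drop(columns=["date"]), tmp_path))

    def test_bad_date_reports_row(self, tiny_records, tmp_path):
        bad = tiny_records.copy()
        bad.loc[2, "date"] = "not-a-date"
        with pytest.raises(ValueError, match="row 3"):
            read_sightings(_write(bad, tmp_path))

    def test_unknown_area_rejected(self, tiny_records, tmp_path):
        bad = tiny_records.copy()
        bad.loc[0, "area"] = "XXXX"
        with pytest.raises(ValueError, match="XXXX"):
            read_sightings(_write(bad, tmp_path))


class TestBuildHistories:
    def test_row_definition(self, tiny_records):
        chs, meta = build_histories(tiny_records, (2010, 2016))
        row = chs.x[list(chs.ids).index("A")]
        assert row.tolist() == [1, 0, 1, 0, 1, 0, 0]

    def test_calf_first_sighting_dropped(self, tiny_records):
        recs = tiny_records.copy()
        recs.loc[recs["individual_id"] == "C", "calf"] = True
        chs, _ = build_histories(recs, (2010, 2016), exclude_calves=True)
        assert "C" not in chs.ids

    def test_releases_match_brute_force_tally(self):
        sim = simulate(scenario_presets("null_homogeneous"), seed=5)
        recs = sim.sightings
        chs, _ = build_histories(
            recs, (int(chs_years := sim.histories.years[0]), int(sim.histories.years[-1]))
        )
        rec_years = pd.to_datetime(recs["date"]).dt.year
        for t, y in enumerate(chs.years):
            expected = recs.loc[rec_years == y, "individual_id"].nunique()
            assert chs.releases_per_occasion[t] == expected

    def test_empty_after_filter_errors(self, tiny_records):
        recs = tiny_records.copy()
        recs["calf"] = True
        with pytest.raises(ValueError):
            build_histories(recs, (2010, 2016))

    def test_roundtrip_through_csv(self, tmp_path):
        sim = simulate(scenario_presets("null_homogeneous"), seed=9)
        path = tmp_path / "sim.csv"
        write_sightings(sim.sightings, path)
        recs = read_sightings(path)
        chs, _ = build_histories(
            recs, (int(sim.histories.years[0]), int(sim.histories.years[-1]))
        )
        orig = sim.histories
        order = np.argsort(orig.ids)
        assert np.array_equal(chs.x, orig.x[order])


class TestSexedSubset:
    def test_biopsy_truncates_earlier_sightings(self):
        recs = pd.DataFrame(
            {
                "individual_id": ["A"] * 3,
                "date": ["1992-06-01", "1995-06-01", "1998-06-01"],
                "area": "JCP",
                "calf": False,
                "sex": "F",
                "biopsy_year": 1995,
            }
        )
        chs, meta = build_histories(recs, (1990, 1999))
        sub, _ = sexed_subset(chs, meta)
        assert sub.x[0].tolist() == [0, 0, 0, 0, 0, 1, 0, 0, 1, 0]

    def test_singleton_history_retained(self):
        recs = pd.DataFrame(
            {
                "individual_id": ["A", "A"],
                "date": ["1992-06-01", "1995-06-01"],
                "area": "JCP",
                "calf": False,
                "sex": "M",
                "biopsy_year": 1995,
            }
        )
        chs, meta = build_histories(recs, (1990, 1999))
        sub, _ = sexed_subset(chs, meta)
        assert sub.n_individuals == 1
        assert sub.x.sum() == 1

    def test_unknown_sex_excluded(self, tiny_records):
        chs, meta = build_histories(tiny_records, (2010, 2016))
        sub, _ = sexed_subset(chs, meta)
        assert "C" not in sub.ids


@pytest.mark.parametrize(
    "row, expected_m, expected_applicable",
    [
        ([1, 1, 0, 1], [1, 1, 0], [True, True, True]),
        ([0, 0, 1, 0], [None, None, 1], [False, False, True]),
        ([1, 1, 1, 1], [1, 1, 1], [True, True, True]),
    ],
)
def test_trap_covariates_definition(row, expected_m, expected_applicable):
    chs = CaptureHistorySet(
        np.array([row]), np.array(["a"]), np.arange(2000, 2000 + len(row))
    )
    m, applicable = trap_covariates(chs)
    assert applicable[0, 1:].tolist() == expected_applicable
    for t, exp in enumerate(expected_m, start=1):
        if exp is not None:
            assert m[0, t] == exp


@pytest.mark.parametrize(
    "row, expected",
    [([0, 1, 0, 1], [0, 1, 0, 0]), ([1, 0, 0, 0], [1, 0, 0, 0])],
)
def test_transient_covariates_definition(row, expected):
    chs = CaptureHistorySet(
        np.array([row]), np.array(["a"]), np.arange(2000, 2004)
    )
    assert transient_covariates(chs)[0].tolist() == expected


def test_transient_row_sums_are_one(null_sim):
    trans = transient_covariates(null_sim.histories)
    assert (trans.sum(axis=1) == 1).all()


class TestTruncate:
    def test_identity(self, null_sim):
        out = truncate(null_sim.histories, 0)
        assert np.array_equal(out.x, null_sim.histories.x)

    def test_drops_late_first_sightings(self):
        x = np.array([[1, 0, 0, 0], [0, 0, 0, 1]])
        chs = CaptureHistorySet(x, np.array(["a", "b"]), np.arange(2000, 2004))
        out = truncate(chs, 1)
        assert list(out.ids) == ["a"]

    def test_too_large_errors(self, null_sim):
        with pytest.raises(ValueError):
            truncate(null_sim.histories, null_sim.histories.n_occasions - 1)

    @given(a=st.integers(0, 3), b=st.integers(0, 3))
    @settings(deadline=None, derandomize=True, max_examples=16)
    def test_composition(self, a, b):
        rng = np.random.default_rng(0)
        x = (rng.random((40, 12)) < 0.3).astype(np.int8)
        x[x.sum(axis=1) == 0, 0] = 1
        chs = CaptureHistorySet(
            x, np.array([f"i{k}" for k in range(40)]), np.arange(2000, 2012)
        )
        once = truncate(chs, a + b)
        twice = truncate(truncate(chs, a), b)
        assert np.array_equal(once.x, twice.x)
        assert list(once.ids) == list(twice.ids)


class TestAreaExchange:
    def test_brute_force_subset_counts(self):
        rng = np.random.default_rng(3)
        areas = ["JCP", "GASP", "ESTU", "SIPM"]
        rows = []
        expected = {}
        ind = 0
        # all 15 nonempty subsets, random multiplicities
        for mask in range(1, 16):
            subset = tuple(sorted(a for k, a in enumerate(areas) if mask >> k & 1))
            count = int(rng.integers(1, 5))
            expected[subset] = count
            for _ in range(count):
                for a in subset:
                    rows.append((f"I{ind}", f"2010-06-{1 + len(rows) % 28:02d}", a))
                ind += 1
        recs = pd.DataFrame(rows, columns=["individual_id", "date", "area"])
        table, summary = area_exchange_summary(recs)
        got = {
            tuple(r["areas"].split("+")): r["n_individuals"]
            for _, r in table.iterrows()
        }
        assert got == expected
        multi = sum(v for k, v in expected.items() if len(k) > 1)
        total = sum(expected.values())
        assert summary["multi_area_total"] == multi
        assert summary["multi_area_proportion"] == pytest.approx(multi / total)

    def test_single_area_degenerate(self, tiny_records):
        _, summary = area_exchange_summary(tiny_records)
        assert summary["multi_area_proportion"] == 0.0
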