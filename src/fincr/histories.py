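"""Sighting records and annual capture-history matrices.

A photo-identification survey yields one row per confirmed sighting of an
identified individual (id, date, area, calf flag, sex).  Mark-recapture
analyses work on the derived binary individual x occasion matrix, where an
occasion is one field season (calendar year).  This module parses sighting
files, applies the standard filters (calf exclusion, biopsy-conditioned
entry for the sexed subset), and derives the individual time-varying
covariates used by trap-dependence and transience model terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AREA_CODES",
    "CaptureHistorySet",
    "read_sightings",
    "build_histories",
    "sexed_subset",
    "trap_covariates",
    "transient_covariates",
    "truncate",
    "area_exchange_summary",
    "write_histories",
    "write_sightings",
]

AREA_CODES = frozenset({"JCP", "GASP", "ESTU", "SIPM"})
SEX_CODES = frozenset({"F", "M", "U"})

REQUIRED_COLUMNS = ("individual_id", "date", "area", "calf", "sex")


@dataclass
class CaptureHistorySet:
    """Binary individual x occasion capture matrix with year labels.

    Every row has at least one capture, and occasion labels are consecutive
    calendar years.  ``releases_per_occasion[t]`` is the number of animals
    captured (and hence released) at occasion ``t``.
    """

    x: np.ndarray
    ids: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int8)
        self.ids = np.asarray(self.ids)
        self.years = np.asarray(self.years, dtype=int)
        if self.x.ndim != 2:
            raise ValueError("capture matrix must be 2-d")
        if self.x.shape != (len(self.ids), len(self.years)):
            raise ValueError("shape mismatch between x, ids, years")
        if len(self.years) >= 2 and not np.all(np.diff(self.years) == 1):
            raise ValueError("occasion years must be consecutive")
        if self.x.shape[0] and not np.all(self.x.sum(axis=1) >= 1):
            raise ValueError("every capture history must contain >=1 capture")

    @property
    def n_individuals(self) -> int:
        return self.x.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.x.shape[1]

    @property
    def first_capture(self) -> np.ndarray:
        """0-based occasion index of each individual's first capture."""
        return np.argmax(self.x == 1, axis=1)

    @property
    def last_capture(self) -> np.ndarray:
        T = self.n_occasions
        return T - 1 - np.argmax(self.x[:, ::-1] == 1, axis=1)

    @property
    def releases_per_occasion(self) -> np.ndarray:
        return self.x.sum(axis=0).astype(int)

    @property
    def effective_sample_size(self) -> int:
        """Total releases over non-terminal occasions (MARK's AICc n)."""
        return int(self.x[:, :-1].sum())

    def subset(self, mask: np.ndarray) -> "CaptureHistorySet":
        return CaptureHistorySet(self.x[mask], self.ids[mask], self.years)


def read_sightings(path, area_codes=AREA_CODES) -> pd.DataFrame:
    """Read a sightings CSV into a validated record table.

    The file must declare ``individual_id, date, area, calf, sex`` columns
    (an optional ``biopsy_year`` column is carried through).  Same
    (individual, date, area) duplicates are collapsed and rows are sorted
    by individual then date.
    """
    df = pd.read_csv(path, dtype={"individual_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sightings file missing required column(s): {missing}")

    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        bad = df.index[parsed.isna()][0]
        raise ValueError(
            f"unparseable date {df.loc[bad, 'date']!r} at data row {bad + 1}"
        )
    df = df.copy()
    df["date"] = parsed

    unknown = set(df["area"].unique()) - set(area_codes)
    if unknown:
        raise ValueError(f"unknown area code(s): {sorted(unknown)}")

    df["calf"] = df["calf"].astype(bool)
    df["sex"] = df["sex"].fillna("U").astype(str)
    bad_sex = set(df["sex"].unique()) - SEX_CODES
    if bad_sex:
        raise ValueError(f"unknown sex code(s): {sorted(bad_sex)}")

    df = df.drop_duplicates(subset=["individual_id", "date", "area"])
    df = df.sort_values(["individual_id", "date"], kind="mergesort")
    return df.reset_index(drop=True)


def write_sightings(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out["calf"] = out["calf"].astype(bool)
    out.to_csv(path, index=False)


def build_histories(
    records: pd.DataFrame,
    year_range: tuple[int, int],
    exclude_calves: bool = True,
) -> tuple[CaptureHistorySet, pd.DataFrame]:
    """Collapse sighting records into an annual capture-history matrix.

    ``x[i, t] = 1`` iff individual ``i`` has >=1 record in year ``t``.
    Individuals whose first-ever sighting is flagged as a calf are dropped
    entirely when ``exclude_calves`` is set (calf observations are
    conditional on the mother's presence, so calves carry no independent
    capture information).  Individuals with no records inside the year
    range are dropped.  Returns the history set and a per-individual
    metadata table (sex, calf-at-first-sighting, first year, days seen,
    biopsy year when recorded); filter counts are stored in
    ``meta.attrs['filter_log']``.
    """
    y0, y1 = year_range
    if y1 - y0 + 1 < 2:
        raise ValueError("year_range must span at least 2 years")

    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec["year"] = rec["date"].dt.year
    n_input = rec["individual_id"].nunique()
    log: dict[str, int] = {"input_individuals": n_input}

    # calf status is judged on the first sighting over the FULL record set
    first = rec.sort_values("date").groupby("individual_id").first()
    calf_at_first = first["calf"]
    if exclude_calves:
        calf_ids = set(calf_at_first.index[calf_at_first])
        rec = rec[~rec["individual_id"].isin(calf_ids)]
        log["dropped_calves"] = len(calf_ids)

    in_range = rec[(rec["year"] >= y0) & (rec["year"] <= y1)]
    kept_ids = np.array(sorted(in_range["individual_id"].unique()))
    log["dropped_outside_years"] = rec["individual_id"].nunique() - len(kept_ids)
    if len(kept_ids) == 0:
        raise ValueError("no individuals remain after filtering")

    years = np.arange(y0, y1 + 1)
    x = np.zeros((len(kept_ids), len(years)), dtype=np.int8)
    idx = {i: k for k, i in enumerate(kept_ids)}
    for iid, yr in zip(in_range["individual_id"], in_range["year"]):
        x[idx[iid], yr - y0] = 1
    chs = CaptureHistorySet(x, kept_ids, years)

    grp = in_range.groupby("individual_id")
    sex = grp["sex"].agg(lambda s: next((v for v in s if v != "U"), "U"))
    meta = pd.DataFrame(
        {
            "sex": sex.reindex(kept_ids).values,
            "calf_at_first_sighting": calf_at_first.reindex(kept_ids)
            .fillna(False)
            .values,
            "first_year": grp["year"].min().reindex(kept_ids).values,
            "days_seen": grp["date"]
            .agg(lambda s: s.dt.normalize().nunique())
            .reindex(kept_ids)
            .values,
        },
        index=pd.Index(kept_ids, name="individual_id"),
    )
    if "biopsy_year" in in_range.columns:
        meta["biopsy_year"] = grp["biopsy_year"].min().reindex(kept_ids).values
    meta.attrs["filter_log"] = log
    return chs, meta


def sexed_subset(
    chs: CaptureHistorySet, meta: pd.DataFrame
) -> tuple[CaptureHistorySet, pd.DataFrame]:
    """Restrict to individuals of known sex, entering at their biopsy year.

    Sex is known only for biopsied animals; to avoid conditioning capture
    histories on a future event, each sexed individual is treated as
    entering the study in its biopsy year and earlier sightings are
    discarded.  Rows that become all-zero are dropped.
    """
    meta = meta.loc[np.asarray(chs.ids)]
    known = meta["sex"].isin(["F", "M"]).to_numpy()
    x = chs.x[known].copy()
    ids = chs.ids[known]
    sub = meta.loc[known].copy()

    if "biopsy_year" in sub.columns:
        biopsy = sub["biopsy_year"].fillna(sub["first_year"]).to_numpy()
    else:
        biopsy = sub["first_year"].to_numpy()
    for i, by in enumerate(biopsy):
        cut = int(by) - chs.years[0]
        if cut > 0:
            x[i, : min(cut, x.shape[1])] = 0

    nonzero = x.sum(axis=1) >= 1
    out = CaptureHistorySet(x[nonzero], ids[nonzero], chs.years)
    return out, sub.loc[nonzero]


def trap_covariates(chs: CaptureHistorySet) -> tuple[np.ndarray, np.ndarray]:
    """Immediate trap-dependence dummy: was the animal captured at t-1?

    Returns ``(m, applicable)`` where ``m[i, t] = x[i, t-1]`` and
    ``applicable[i, t]`` is True exactly for occasions strictly after the
    first capture (the covariate has no meaning at or before release).
    """
    m = np.zeros_like(chs.x)
    m[:, 1:] = chs.x[:, :-1]
    t = np.arange(chs.n_occasions)
    applicable = t[None, :] > chs.first_capture[:, None]
    return m, applicable


def transient_covariates(chs: CaptureHistorySet) -> np.ndarray:
    """Transience dummy: 1 at the first sighting occasion, 0 elsewhere."""
    trans = np.zeros_like(chs.x)
    trans[np.arange(chs.n_individuals), chs.first_capture] = 1
    return trans


def truncate(chs: CaptureHistorySet, drop_last: int) -> CaptureHistorySet:
    """Drop the last ``drop_last`` occasions and prune emptied histories."""
    if drop_last < 0 or drop_last >= chs.n_occasions - 1:
        raise ValueError("drop_last must be in [0, n_occasions - 2]")
    if drop_last == 0:
        return CaptureHistorySet(chs.x.copy(), chs.ids.copy(), chs.years.copy())
    x = chs.x[:, : chs.n_occasions - drop_last]
    keep = x.sum(axis=1) >= 1
    return CaptureHistorySet(x[keep], chs.ids[keep], chs.years[: -drop_last])


def area_exchange_summary(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Count individuals per combination of areas they were seen in.

    Returns a table with one row per nonempty area subset observed, plus a
    summary with single-area and multi-area totals and the multi-area
    proportion.
    """
    per_ind = records.groupby("individual_id")["area"].agg(
        lambda s: tuple(sorted(set(s)))
    )
    counts = per_ind.value_counts()
    table = pd.DataFrame(
        {
            "areas": ["+".join(c) for c in counts.index],
            "n_areas": [len(c) for c in counts.index],
            "n_individuals": counts.values,
        }
    ).sort_values(["n_areas", "areas"], kind="mergesort").reset_index(drop=True)
    single = int(table.loc[table["n_areas"] == 1, "n_individuals"].sum())
    multi = int(table.loc[table["n_areas"] > 1, "n_individuals"].sum())
    total = single + multi
    summary = {
        "single_area_total": single,
        "multi_area_total": multi,
        "multi_area_proportion": multi / total if total else 0.0,
    }
    return table, summary


def write_histories(chs: CaptureHistorySet, path, meta: pd.DataFrame | None = None):
    """Export the capture matrix as CSV plus a JSON metadata sidecar."""
    df = pd.DataFrame(chs.x, index=chs.ids, columns=chs.years)
    df.index.name = "individual_id"
    df.to_csv(path)
    sidecar = {
        "n_individuals": int(chs.n_individuals),
        "n_occasions": int(chs.n_occasions),
        "years": [int(y) for y in chs.years],
        "releases_per_occasion": [int(v) for v in chs.releases_per_occasion],
    }
    if meta is not None and "filter_log" in meta.attrs:
        sidecar["filter_log"] = meta.attrs["filter_log"]
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
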