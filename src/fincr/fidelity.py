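"""Site-fidelity indices, Ward clustering, and fidelity-group comparisons.

Two per-individual indices summarize residency: the annual sighting rate
(years seen / years elapsed since first sighting, inclusive) and the survey
sighting rate (days seen / survey days carried out since the first
sighting).  After robust (median/MAD) standardization the two indices feed
an agglomerative hierarchical clustering under Ward's minimum-variance
criterion with Euclidean dissimilarity; cutting the tree at its top split
separates a high-fidelity "core regular" group from low-fidelity
"occasional visitors".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy import stats

__all__ = [
    "EffortLog",
    "ClusterResult",
    "fidelity_indices",
    "robust_standardize",
    "ward_linkage",
    "cut_two_groups",
    "group_comparisons",
]

CORE = "core_regular"
OCCASIONAL = "occasional_visitor"


@dataclass
class EffortLog:
    """Survey effort: days surveyed per year, optionally the actual dates.

    When ``survey_dates`` is available the survey-rate denominator can be
    counted from an individual's first sighting date; otherwise whole-year
    totals from the first-sighting year are used.
    """

    survey_days: dict[int, int]
    survey_dates: dict[int, list] | None = None

    def covers(self, years) -> bool:
        return all(int(y) in self.survey_days for y in years)

    def days_between(self, first_date, last_year: int) -> int:
        first_date = pd.Timestamp(first_date)
        y0 = first_date.year
        if self.survey_dates is not None:
            n = sum(
                1
                for y in range(y0, last_year + 1)
                for d in self.survey_dates.get(y, [])
                if pd.Timestamp(d) >= first_date
            )
            return n
        return sum(self.survey_days[y] for y in range(y0, last_year + 1))


def fidelity_indices(
    records: pd.DataFrame,
    effort: EffortLog,
    last_year: int,
    min_tenure_cutoff_year: int | None = None,
) -> pd.DataFrame:
    """Annual and survey sighting rates per individual.

    Individuals first identified after ``min_tenure_cutoff_year``
    (default: ``last_year - 5``) are excluded because too little time has
    passed to measure fidelity.  Both denominators start at the first
    sighting (inclusive), so an individual seen at least once every year
    has an annual rate of exactly 1.
    """
    if min_tenure_cutoff_year is None:
        min_tenure_cutoff_year = last_year - 5

    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec = rec[rec["date"].dt.year <= last_year]
    if rec.empty:
        raise ValueError("no sightings at or before last_year")
    if not effort.covers(range(int(rec["date"].dt.year.min()), last_year + 1)):
        raise ValueError("effort log does not cover all study years")

    grp = rec.groupby("individual_id")
    first_date = grp["date"].min()
    first_year = first_date.dt.year
    if (first_year > last_year).any():
        raise ValueError("individual first seen after last_year")
    years_seen = grp["date"].agg(lambda s: s.dt.year.nunique())
    days_seen = grp["date"].agg(lambda s: s.dt.normalize().nunique())

    tenure_years = last_year - first_year + 1
    survey_days = pd.Series(
        [effort.days_between(d, last_year) for d in first_date],
        index=first_date.index,
    )

    out = pd.DataFrame(
        {
            "first_year": first_year,
            "years_seen": years_seen,
            "annual_rate": years_seen / tenure_years,
            "days_seen": days_seen,
            "survey_days_since_first": survey_days,
            "survey_rate": days_seen / survey_days,
        }
    )
    out = out[out["first_year"] <= min_tenure_cutoff_year]
    if out.empty:
        raise ValueError("no individuals remain after the tenure cutoff")
    out.index.name = "individual_id"
    return out


def robust_standardize(values, mad_constant: float = 1.0) -> np.ndarray:
    """Center on the median and scale by the median absolute deviation.

    ``mad_constant`` rescales the MAD (1.4826 gives normal-consistency;
    the default 1.0 is the raw MAD).  Raises if the MAD is zero, in which
    case a caller should fall back to a different scale measure.
    """
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med)) * mad_constant
    if mad == 0:
        raise ValueError(
            "median absolute deviation is zero; standardization undefined "
            "(consider an IQR- or SD-based scale instead)"
        )
    return (v - med) / mad


@dataclass
class ClusterResult:
    """Ward merge tree with a 2-group cut and per-group summaries."""

    merge_tree: np.ndarray  # scipy linkage matrix
    labels: pd.Series  # individual_id -> CORE / OCCASIONAL
    group_summaries: pd.DataFrame


def ward_linkage(points: np.ndarray, variant: str = "ward") -> np.ndarray:
    """Agglomerative Ward merge tree on 2-d standardized index pairs.

    ``variant='ward'`` is Ward's minimum-variance criterion on Euclidean
    distances with the squared-distance Lance-Williams update (scipy /
    hclust ward.D2).  ``variant='ward_d'`` applies the Lance-Williams
    recurrence to unsquared distances (hclust ward.D), kept because the
    two variants can split borderline individuals differently.
    Ties are broken toward the lowest pair of cluster indices.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need >=2 points in >=1 dimensions")
    if variant == "ward":
        return linkage(pts, method="ward")
    if variant != "ward_d":
        raise ValueError(f"unknown Ward variant {variant!r}")
    return _lance_williams_ward(squareform(pdist(pts)))


def _lance_williams_ward(d: np.ndarray) -> np.ndarray:
    """Ward recurrence applied directly to the given dissimilarities."""
    n = d.shape[0]
    d = d.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    size = np.ones(n)
    active = list(range(n))
    cluster_id = list(range(n))
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = d[np.ix_(active, active)]
        k = np.argmin(sub)  # row-major => lowest-index tie-break
        i_loc, j_loc = divmod(k, sub.shape[1])
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        h = d[i, j]
        ni, nj = size[i], size[j]
        Z[step] = (cluster_id[i], cluster_id[j], h, ni + nj)
        # Lance-Williams (Ward): d(ij,k) from d(i,k), d(j,k), d(i,j)
        for m in active:
            if m in (i, j):
                continue
            nm = size[m]
            tot = ni + nj + nm
            d_new = (
                (ni + nm) / tot * d[i, m]
                + (nj + nm) / tot * d[j, m]
                - nm / tot * h
            )
            d[i, m] = d[m, i] = d_new
        size[i] = ni + nj
        cluster_id[i] = n + step
        active.remove(j)
    return Z


def cut_two_groups(
    tree: np.ndarray, indices: pd.DataFrame, k: int = 2
) -> ClusterResult:
    """Cut the merge tree at its top split and label the groups.

    The group with the higher mean annual sighting rate is labelled
    ``core_regular``.  Group summaries report n, mean, and SE of each
    index.  ``k != 2`` cuts into k groups but keeps numeric labels (the
    core/occasional naming only makes sense for a 2-way cut).
    """
    assign = fcluster(tree, t=k, criterion="maxclust")
    labels = pd.Series(assign, index=indices.index, name="group")
    if k == 2 and labels.nunique() == 2:
        means = indices.groupby(labels)["annual_rate"].mean()
        core_id = means.idxmax()
        labels = labels.map(lambda g: CORE if g == core_id else OCCASIONAL)

    rows = []
    for g, sub in indices.groupby(labels):
        row = {"group": g, "n": len(sub)}
        for col in ("annual_rate", "survey_rate"):
            row[f"mean_{col}"] = sub[col].mean()
            row[f"se_{col}"] = sub[col].std(ddof=1) / np.sqrt(len(sub)) if len(sub) > 1 else np.nan
        rows.append(row)
    summaries = pd.DataFrame(rows).set_index("group")
    return ClusterResult(tree, labels, summaries)


def group_comparisons(
    labels: pd.Series, indices: pd.DataFrame, sex: pd.Series | None = None
) -> dict:
    """Welch two-sample t tests on each index and a sex-ratio chi-square.

    The t statistic uses unequal variances with Welch-Satterthwaite df.
    The sex comparison is a 2-sample test of equal proportions: Pearson
    chi-square with Yates continuity correction on the 2x2 (group x sex)
    table of known-sex individuals.
    """
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError("group comparison requires exactly two groups")
    a_ids = labels.index[labels == groups[0]]
    b_ids = labels.index[labels == groups[1]]
    out: dict = {}
    for col in ("annual_rate", "survey_rate"):
        a = indices.loc[a_ids, col].to_numpy()
        b = indices.loc[b_ids, col].to_numpy()
        if np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0:
            raise ValueError(f"zero variance in {col} within a group")
        res = stats.ttest_ind(a, b, equal_var=False)
        out[col] = {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}
    if sex is not None:
        known = sex[sex.isin(["F", "M"])]
        tab = pd.crosstab(labels.loc[known.index], known)
        chi2, p, df, _ = stats.chi2_contingency(tab.to_numpy(), correction=True)
        out["sex_ratio"] = {"chi2": float(chi2), "df": int(df), "p": float(p)}
    return out
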