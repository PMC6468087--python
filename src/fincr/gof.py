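"""Contingency-table goodness-of-fit tests for the time-dependent CJS model.

The classic U-CARE-style decomposition: Test3.SR contrasts newly marked
against previously marked animals in their probability of ever being seen
again (sensitive to transients); Test3.SM contrasts the timing of the next
sighting for the same split; Test2.CT contrasts capture at t+1 between
animals captured and not captured at t among animals known alive on both
sides (sensitive to immediate trap-dependence / Markovian temporary
emigration); Test2.CL does the same for later recaptures.  Components are
Pearson chi-squares on per-occasion 2x2 tables; tables with any expected
cell below 2 are uninformative at the 2x2 level and are dropped from the
sum.  The overdispersion factor c-hat is the overall chi-square divided by
its degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .histories import CaptureHistorySet

__all__ = [
    "MArray",
    "ComponentResult",
    "GofReport",
    "m_array",
    "test3sr",
    "test3sm",
    "test2ct",
    "test2cl",
    "overall_gof",
]

MIN_EXPECTED = 2.0


@dataclass
class MArray:
    """Reduced m-array: releases per occasion and first-recapture counts.

    ``m[t, j]`` counts animals released at occasion ``t`` whose first
    subsequent capture was at occasion ``j`` (releases include the
    re-release of every recaptured animal).
    """

    releases: np.ndarray  # (T-1,)
    m: np.ndarray  # (T-1, T)

    @property
    def never_seen_again(self) -> np.ndarray:
        return self.releases - self.m.sum(axis=1)


def m_array(chs: CaptureHistorySet) -> MArray:
    x = chs.x
    n, T = x.shape
    releases = x[:, :-1].sum(axis=0).astype(int)
    m = np.zeros((T - 1, T), dtype=int)
    for i in range(n):
        caps = np.flatnonzero(x[i])
        for a, b in zip(caps[:-1], caps[1:]):
            if a < T - 1:
                m[a, b] += 1
    return MArray(releases, m)


@dataclass
class ComponentResult:
    name: str
    chi2: float
    df: int
    p: float
    z: float  # signed directional statistic (positive = excess in cell 11)
    tables: list = field(default_factory=list)


def _chi2_2x2(table: np.ndarray):
    """Pearson chi-square (no correction) for one 2x2 table.

    Returns (chi2, signed_z, informative): uninformative when a margin is
    zero or any expected cell is below ``MIN_EXPECTED`` (pooling a 2x2
    below 2x2 destroys the contrast, so such tables are dropped).
    """
    table = np.asarray(table, dtype=float)
    rs = table.sum(axis=1)
    cs = table.sum(axis=0)
    N = table.sum()
    if N == 0 or np.any(rs == 0) or np.any(cs == 0):
        return 0.0, 0.0, False
    expected = np.outer(rs, cs) / N
    if expected.min() < MIN_EXPECTED:
        return 0.0, 0.0, False
    chi2 = float(((table - expected) ** 2 / expected).sum())
    sign = np.sign(table[0, 0] - expected[0, 0])
    return chi2, float(sign * np.sqrt(chi2)), True


def _component(name: str, tables: list[np.ndarray]) -> ComponentResult:
    chi2 = 0.0
    df = 0
    zsum = 0.0
    kept = []
    for tab in tables:
        c, z, ok = _chi2_2x2(tab)
        if ok:
            chi2 += c
            zsum += z
            df += 1
            kept.append(tab)
    if df == 0:
        import warnings

        warnings.warn(f"{name}: no informative table; chi2 = 0, df = 0", stacklevel=3)
        return ComponentResult(name, 0.0, 0, np.nan, 0.0, kept)
    p = float(stats.chi2.sf(chi2, df))
    return ComponentResult(name, chi2, df, p, zsum / np.sqrt(df), kept)


def _occasion_flags(chs: CaptureHistorySet):
    x = chs.x.astype(bool)
    f = chs.first_capture
    T = chs.n_occasions
    seen_after = np.zeros_like(x)
    seen_after[:, :-1] = np.cumsum(x[:, ::-1], axis=1)[:, ::-1][:, 1:] > 0
    return x, f, T, seen_after


def test3sr(chs: CaptureHistorySet) -> ComponentResult:
    """Newly vs previously marked x ever seen again (transience signal).

    The signed statistic is negative when newly marked animals are seen
    again less often than expected (the transient direction).
    """
    if chs.n_occasions < 3:
        raise ValueError("need >= 3 occasions")
    x, f, T, seen_after = _occasion_flags(chs)
    tables = []
    for t in range(1, T - 1):
        at_t = x[:, t]
        new = at_t & (f == t)
        old = at_t & (f < t)
        again = seen_after[:, t]
        # rows: new, old; cols: seen again, never -- the signed statistic
        # is then negative when newly marked animals disappear (transience)
        tab = np.array(
            [
                [(new & again).sum(), (new & ~again).sum()],
                [(old & again).sum(), (old & ~again).sum()],
            ]
        )
        tables.append(tab)
    return _component("Test3.SR", tables)


def test3sm(chs: CaptureHistorySet) -> ComponentResult:
    """Newly vs previously marked x timing of next sighting."""
    if chs.n_occasions < 3:
        raise ValueError("need >= 3 occasions")
    x, f, T, seen_after = _occasion_flags(chs)
    nxt = _next_capture(chs)
    tables = []
    for t in range(1, T - 1):
        at_t = x[:, t] & seen_after[:, t]
        new = at_t & (f == t)
        old = at_t & (f < t)
        imm = nxt[:, t] == t + 1
        tab = np.array(
            [
                [(new & imm).sum(), (new & ~imm).sum()],
                [(old & imm).sum(), (old & ~imm).sum()],
            ]
        )
        tables.append(tab)
    return _component("Test3.SM", tables)


def _next_capture(chs: CaptureHistorySet) -> np.ndarray:
    """nxt[i, t]: occasion of i's first capture after t (T if none)."""
    x = chs.x
    n, T = x.shape
    nxt = np.full((n, T), T, dtype=int)
    for t in range(T - 2, -1, -1):
        nxt[:, t] = np.where(x[:, t + 1] == 1, t + 1, nxt[:, t + 1])
    return nxt


def test2ct(chs: CaptureHistorySet) -> ComponentResult:
    """Captured vs not captured at t x recaptured at t+1 vs later.

    Restricted to animals marked at or before t and known alive afterwards
    (a later capture exists).  A positive signed statistic means animals
    captured at t are over-represented among t+1 captures: trap-happiness
    (or sticky in-area presence under Markovian temporary emigration).
    """
    if chs.n_occasions < 3:
        raise ValueError("need >= 3 occasions")
    x, f, T, seen_after = _occasion_flags(chs)
    nxt = _next_capture(chs)
    tables = []
    for t in range(1, T - 1):
        marked = f <= t
        alive_later = seen_after[:, t]
        base = marked & alive_later
        cap = base & x[:, t]
        noncap = base & ~x[:, t]
        imm = nxt[:, t] == t + 1
        tab = np.array(
            [
                [(cap & imm).sum(), (cap & ~imm).sum()],
                [(noncap & imm).sum(), (noncap & ~imm).sum()],
            ]
        )
        tables.append(tab)
    return _component("Test2.CT", tables)


def test2cl(chs: CaptureHistorySet) -> ComponentResult:
    """Captured vs not captured at t x next recapture at t+2 vs later.

    Same conditioning as Test2.CT but among animals whose next capture is
    after t+1, probing longer-range dependence.
    """
    if chs.n_occasions < 4:
        raise ValueError("need >= 4 occasions")
    x, f, T, seen_after = _occasion_flags(chs)
    nxt = _next_capture(chs)
    tables = []
    for t in range(1, T - 2):
        base = (f <= t) & (nxt[:, t] >= t + 2) & (nxt[:, t] < T)
        cap = base & x[:, t]
        noncap = base & ~x[:, t]
        imm = nxt[:, t] == t + 2
        tab = np.array(
            [
                [(cap & imm).sum(), (cap & ~imm).sum()],
                [(noncap & imm).sum(), (noncap & ~imm).sum()],
            ]
        )
        tables.append(tab)
    return _component("Test2.CL", tables)


@dataclass
class GofReport:
    components: dict[str, ComponentResult]
    chi2: float
    df: int
    p: float
    c_hat: float

    def as_dict(self) -> dict:
        return {
            "components": {
                k: {"chi2": c.chi2, "df": c.df, "p": c.p, "z": c.z}
                for k, c in self.components.items()
            },
            "overall": {"chi2": self.chi2, "df": self.df, "p": self.p},
            "c_hat": self.c_hat,
        }


def overall_gof(chs: CaptureHistorySet) -> GofReport:
    """All four components, their sum, and the overdispersion factor."""
    if chs.n_occasions < 4:
        raise ValueError("need >= 4 occasions")
    comps = {
        c.name: c
        for c in (test3sr(chs), test3sm(chs), test2ct(chs), test2cl(chs))
    }
    chi2 = sum(c.chi2 for c in comps.values())
    df = sum(c.df for c in comps.values())
    if df == 0:
        raise ValueError("overall GOF undefined: zero degrees of freedom")
    p = float(stats.chi2.sf(chi2, df))
    return GofReport(comps, chi2, df, p, chi2 / df)
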