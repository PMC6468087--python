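"""Model grammar and design matrices for survival/recapture structures.

Parameter structures follow the standard open-population notation:
constant ``.``/``1``, fully time-dependent ``t``, linear temporal trend
``T``, flexible B-spline trend ``spline(k)``, sex ``s``, immediate
trap-dependence ``m`` (recapture only), and transience ``trans``
(survival offset on the interval following first sighting).  Additive
terms combine with ``+``; the supported interactions are ``s:T`` (one
trend slope per sex, no sex main effect) and ``trans:T``.

Formulas are written as e.g. ``phi ~ T``, ``p ~ t + m``, ``pent ~ T``.
All parameters use a logit link (multinomial logit for entry
probabilities).  Each linear predictor carries an implicit intercept;
factor terms use treatment contrasts against the first estimable cell.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["ModelSpec", "spline_trend_basis", "build_cjs_design", "CJSDesign"]

_SPLINE_RE = re.compile(r"^spline\((\d+)\)$")

PHI_TERMS = {"1", ".", "t", "T", "s", "trans", "s:T", "trans:T"}
P_TERMS = {"1", ".", "t", "T", "m"}
PENT_TERMS = {"1", ".", "t", "T"}


def _parse_terms(formula: str, allowed: set[str], allow_spline: bool) -> list[str]:
    rhs = formula.split("~")[-1].strip()
    terms = [t.strip() for t in rhs.split("+") if t.strip()]
    if not terms:
        raise ValueError(f"empty formula {formula!r}")
    out = []
    for t in terms:
        if t in (".", "1"):
            continue  # intercept is implicit
        if _SPLINE_RE.match(t):
            if not allow_spline:
                raise ValueError(f"spline term not allowed here: {t!r}")
        elif t not in allowed:
            raise ValueError(f"unknown term {t!r} in formula {formula!r}")
        out.append(t)
    return out


@dataclass(frozen=True)
class ModelSpec:
    """Declarative survival/recapture(/entry) structure.

    ``phi`` and ``p`` are formula strings; ``pent`` is used only by the
    POPAN super-population model.
    """

    phi: str = "~ 1"
    p: str = "~ 1"
    pent: str | None = None

    @property
    def phi_terms(self) -> list[str]:
        return _parse_terms(self.phi, PHI_TERMS, allow_spline=True)

    @property
    def p_terms(self) -> list[str]:
        return _parse_terms(self.p, P_TERMS, allow_spline=False)

    @property
    def pent_terms(self) -> list[str]:
        if self.pent is None:
            return []
        return _parse_terms(self.pent, PENT_TERMS, allow_spline=False)

    @property
    def name(self) -> str:
        def fmt(terms):
            return " + ".join(terms) if terms else "."

        s = f"phi({fmt(self.phi_terms)}) p({fmt(self.p_terms)})"
        if self.pent is not None:
            s += f" pent({fmt(self.pent_terms)})"
        return s


def spline_trend_basis(
    n_points: int, k_knots: int, degree: int = 3
) -> np.ndarray:
    """Cubic (by default) B-spline basis over an equally spaced index.

    Interior knots sit at equally spaced quantiles of the index; boundary
    knots are repeated ``degree + 1`` times, so the ``k + degree + 1``
    columns form a partition of unity (rows sum to 1).  With an explicit
    intercept in the model, drop the first column.
    """
    if k_knots < 0:
        raise ValueError("k_knots must be >= 0")
    if n_points <= degree + k_knots:
        raise ValueError("need n_points > degree + k_knots")
    x = np.arange(n_points, dtype=float)
    interior = np.quantile(x, np.linspace(0, 1, k_knots + 2)[1:-1])
    knots = np.r_[
        np.repeat(x[0], degree + 1), interior, np.repeat(x[-1], degree + 1)
    ]
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def _std_time(J: int) -> np.ndarray:
    t = np.arange(J, dtype=float)
    sd = t.std()
    return (t - t.mean()) / (sd if sd > 0 else 1.0)


@dataclass
class CJSDesign:
    """Per-cell design tensors for a conditional CJS likelihood.

    ``phi_X`` has shape (n, T-1, k_phi) over intervals; ``p_X0``/``p_X1``
    have shape (n, T, k_p) over occasions with the trap-dependence column
    set to 0 / 1 respectively (identical when ``m`` is absent).
    """

    phi_X: np.ndarray
    p_X0: np.ndarray
    p_X1: np.ndarray
    phi_names: list[str]
    p_names: list[str]

    @property
    def k_phi(self) -> int:
        return self.phi_X.shape[2]

    @property
    def k_p(self) -> int:
        return self.p_X0.shape[2]

    @property
    def n_parameters(self) -> int:
        return self.k_phi + self.k_p


def _phi_columns(terms, n, T, sex_code, first_capture):
    """Design columns over survival intervals j = 0..T-2."""
    J = T - 1
    tl = _std_time(J)
    cols = [np.ones((n, J))]
    names = ["phi:(Intercept)"]
    trans_int = np.zeros((n, J))
    rows = first_capture < J
    trans_int[np.arange(n)[rows], first_capture[rows]] = 1.0
    for t in terms:
        m = _SPLINE_RE.match(t)
        if m:
            B = spline_trend_basis(J, int(m.group(1)))[:, 1:]
            for c in range(B.shape[1]):
                cols.append(np.broadcast_to(B[:, c], (n, J)))
                names.append(f"phi:spline{c + 1}")
        elif t == "t":
            for j in range(1, J):
                col = np.zeros((n, J))
                col[:, j] = 1.0
                cols.append(col)
                names.append(f"phi:t{j + 1}")
        elif t == "T":
            cols.append(np.broadcast_to(tl, (n, J)))
            names.append("phi:T")
        elif t == "s":
            if sex_code is None:
                raise ValueError("term 's' requires a sex covariate")
            cols.append(np.broadcast_to(sex_code[:, None], (n, J)))
            names.append("phi:sexM")
        elif t == "s:T":
            if sex_code is None:
                raise ValueError("term 's:T' requires a sex covariate")
            cols.append((1.0 - sex_code)[:, None] * tl[None, :])
            cols.append(sex_code[:, None] * tl[None, :])
            names.extend(["phi:T.F", "phi:T.M"])
        elif t == "trans":
            cols.append(trans_int)
            names.append("phi:trans")
        elif t == "trans:T":
            cols.append(trans_int * tl[None, :])
            names.append("phi:trans.T")
        else:  # pragma: no cover - guarded by the parser
            raise ValueError(t)
    return np.stack(cols, axis=2), names


def _p_columns(terms, n, T, conditional: bool):
    """Design columns over capture occasions t = 0..T-1.

    For the conditional (CJS) likelihood, occasion 0 is never a recapture
    cell, so the time factor's reference level is occasion 1; for the full
    (POPAN) likelihood the reference is occasion 0.
    """
    tl = _std_time(T)
    ref = 1 if conditional else 0
    cols = [np.ones((n, T))]
    names = ["p:(Intercept)"]
    has_m = False
    for t in terms:
        if t == "t":
            for j in range(T):
                if j <= ref:
                    continue
                col = np.zeros((n, T))
                col[:, j] = 1.0
                cols.append(col)
                names.append(f"p:t{j + 1}")
        elif t == "T":
            cols.append(np.broadcast_to(tl, (n, T)))
            names.append("p:T")
        elif t == "m":
            has_m = True
        else:  # pragma: no cover
            raise ValueError(t)
    X0 = np.stack(cols, axis=2)
    if has_m:
        zero = np.zeros((n, T, 1))
        one = np.ones((n, T, 1))
        X1 = np.concatenate([X0, one], axis=2)
        X0 = np.concatenate([X0, zero], axis=2)
        names.append("p:m")
    else:
        X1 = X0
    return X0, X1, names


def build_cjs_design(
    spec: ModelSpec,
    chs,
    sex: np.ndarray | None = None,
    conditional: bool = True,
) -> CJSDesign:
    """Assemble design tensors for the given history set and structure.

    ``sex`` is an array of 'F'/'M' per individual (required by sex terms).
    """
    n, T = chs.x.shape
    sex_code = None
    if sex is not None:
        sex = np.asarray(sex)
        sex_code = (sex == "M").astype(float)
    phi_X, phi_names = _phi_columns(
        spec.phi_terms, n, T, sex_code, chs.first_capture
    )
    p_X0, p_X1, p_names = _p_columns(spec.p_terms, n, T, conditional)
    return CJSDesign(phi_X, p_X0, p_X1, phi_names, p_names)
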