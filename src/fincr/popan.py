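"""POPAN (Schwarz-Arnason) super-population Jolly-Seber likelihood.

Beyond the CJS parameters, the POPAN formulation models per-occasion entry
probabilities ``pent`` (a multinomial-logit vector over occasions summing
to 1, covering both initial presence and later recruitment) and the
super-population size N: the total number of individuals present in the
study area at some point during the analysis window.  N enters through
the never-detected term and is parameterized as D + exp(eta) (D = number
of distinct individuals observed) so the estimate respects its lower
bound; its CI is log-normal on N - D.

Transience is handled as a survival offset on the interval following an
animal's first sighting (the ``trans`` model term), so a pure transient
has near-zero apparent survival immediately after first capture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from .cjs import FitResult, _numerical_hessian, _safe_log, collapse_histories
from .design import ModelSpec, build_cjs_design, _std_time
from .histories import CaptureHistorySet
from .selection import ModelSet, aicc, akaike_weights, qaicc

__all__ = [
    "SuperPopulationEstimate",
    "entry_probabilities",
    "popan_neg_loglik",
    "fit_popan",
    "average_superpopulation",
]

_ETA_CLIP = 30.0

POPAN_PHI_TERMS_OK = {"t", "T", "trans", "trans:T"}


@dataclass
class SuperPopulationEstimate:
    N_hat: float
    se: float
    lcl: float
    ucl: float
    period: tuple[int, int]

    def __post_init__(self):
        assert self.lcl <= self.N_hat <= self.ucl


def entry_probabilities(coefs, structure: str, n_occasions: int) -> np.ndarray:
    """Back-transform entry coefficients to a probability vector.

    ``structure``: '1'/'.' (equal entry, no coefficients), 'T' (one slope
    on a standardized occasion index), or 't' (free logits with the first
    occasion as reference cell).  Always sums to 1.
    """
    coefs = np.asarray(coefs, dtype=float)
    eta = np.zeros(n_occasions)
    if structure in ("1", "."):
        if coefs.size:
            raise ValueError("constant entry structure takes no coefficients")
    elif structure == "T":
        eta = coefs[0] * _std_time(n_occasions)
    elif structure == "t":
        if coefs.size != n_occasions - 1:
            raise ValueError("time-dependent entry needs n_occasions - 1 coefficients")
        eta[1:] = coefs
    else:
        raise ValueError(f"unknown entry structure {structure!r}")
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    w = np.exp(eta - eta.max())
    return w / w.sum()


def _n_pent_coefs(structure: str, T: int) -> int:
    return {"1": 0, ".": 0, "T": 1, "t": T - 1}[structure]


def _pent_structure(spec: ModelSpec) -> str:
    terms = spec.pent_terms
    if not terms:
        return "1"
    if terms == ["T"]:
        return "T"
    if terms == ["t"]:
        return "t"
    raise ValueError(f"unsupported entry structure {terms!r}")


class _PopanDesign:
    """Design pieces for the full open-population likelihood.

    Survival and capture structures must be time-only apart from the
    transience offset, so the pre-entry and never-seen terms reduce to
    per-occasion vectors.
    """

    def __init__(self, spec: ModelSpec, chs: CaptureHistorySet):
        for t in spec.phi_terms:
            if t not in POPAN_PHI_TERMS_OK and not t.startswith("spline"):
                raise ValueError(f"POPAN survival term not supported: {t!r}")
        if "m" in spec.p_terms:
            raise ValueError("trap-dependence is not part of the POPAN structure")
        self.spec = spec
        self.cjs = build_cjs_design(spec, chs, sex=None, conditional=False)
        names = self.cjs.phi_names
        self.trans_cols = np.array(
            [i for i, nm in enumerate(names) if "trans" in nm], dtype=int
        )
        self.pent_structure = _pent_structure(spec)
        self.T = chs.n_occasions
        self.k_phi = self.cjs.k_phi
        self.k_p = self.cjs.k_p
        self.k_pent = _n_pent_coefs(self.pent_structure, self.T)
        self.n_parameters = self.k_phi + self.k_p + self.k_pent + 1

    def split(self, params):
        k1, k2, k3 = self.k_phi, self.k_p, self.k_pent
        return (
            params[:k1],
            params[k1 : k1 + k2],
            params[k1 + k2 : k1 + k2 + k3],
            params[-1],
        )

    def probs(self, params):
        b_phi, b_p, b_pent, eta_N = self.split(params)
        phi = expit(np.clip(self.cjs.phi_X @ b_phi, -_ETA_CLIP, _ETA_CLIP))
        base = self.cjs.phi_X.copy()
        if self.trans_cols.size:
            base[:, :, self.trans_cols] = 0.0
        phi0 = expit(np.clip(base[0] @ b_phi, -_ETA_CLIP, _ETA_CLIP))
        p = expit(np.clip(self.cjs.p_X0[0] @ b_p, -_ETA_CLIP, _ETA_CLIP))
        pent = entry_probabilities(b_pent, self.pent_structure, self.T)
        return phi, phi0, p, pent, eta_N


def popan_neg_loglik(
    params: np.ndarray,
    design: _PopanDesign,
    chs: CaptureHistorySet,
    weights: np.ndarray | None = None,
) -> float:
    """Negative full open-population log-likelihood (up to the D! constant)."""
    x = chs.x
    n, T = x.shape
    if weights is None:
        weights = np.ones(n)
    D = float(weights.sum())
    f = chs.first_capture
    l = chs.last_capture
    phi, phi0, p, pent, eta_N = design.probs(params)
    N = D + np.exp(np.clip(eta_N, -_ETA_CLIP, _ETA_CLIP))

    # psi[t]: P(entered at or before t, survived to t, undetected before t)
    psi = np.zeros(T)
    psi[0] = pent[0]
    for t in range(1, T):
        psi[t] = psi[t - 1] * (1 - p[t - 1]) * phi0[t - 1] + pent[t]

    # zeta[t]: P(never detected at t..T-1 | present at t), baseline survival
    zeta = np.zeros(T)
    zeta[T - 1] = 1 - p[T - 1]
    for t in range(T - 2, -1, -1):
        zeta[t] = (1 - p[t]) * ((1 - phi0[t]) + phi0[t] * zeta[t + 1])
    p_never = float(pent @ zeta)

    # chi0[i, t]: P(never seen after t | alive at t), per-individual phi
    chi0 = np.ones((n, T))
    for t in range(T - 2, -1, -1):
        chi0[:, t] = (1 - phi[:, t]) + phi[:, t] * (1 - p[t + 1]) * chi0[:, t + 1]

    tgrid = np.arange(T)
    between = (tgrid[None, :] > f[:, None]) & (tgrid[None, :] <= l[:, None])
    det = x * _safe_log(p)[None, :] + (1 - x) * _safe_log(1 - p)[None, :]
    jgrid = np.arange(T - 1)
    interval = (jgrid[None, :] >= f[:, None]) & (jgrid[None, :] < l[:, None])

    ll_i = _safe_log(psi[f]) + _safe_log(p[f])
    ll_i += np.where(between, det, 0.0).sum(axis=1)
    ll_i += np.where(interval, _safe_log(phi), 0.0).sum(axis=1)
    ll_i += _safe_log(chi0[np.arange(n), l])

    ll = float(ll_i @ weights)
    ll += (N - D) * _safe_log(np.array([p_never]))[0]
    ll += float(gammaln(N + 1) - gammaln(N - D + 1))
    return -ll


def fit_popan(
    spec: ModelSpec,
    chs: CaptureHistorySet,
    c_hat: float = 1.0,
    n_starts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood POPAN fit with a super-population estimate.

    With overdispersion (c_hat > 1, estimated externally from the CJS
    approximation GOF) the criterion becomes QAICc and SEs are inflated by
    sqrt(c_hat).  The N estimate is attached as
    ``result.extras['N']`` (a SuperPopulationEstimate).
    """
    small, _, weights = collapse_histories(chs)
    design = _PopanDesign(spec, small)
    D = float(weights.sum())
    T = small.n_occasions

    fun = lambda th: popan_neg_loglik(th, design, small, weights)
    K = design.n_parameters
    rng = np.random.default_rng(seed)
    eta0 = np.log(max(0.3 * D, 5.0))
    best = None
    for s in range(max(1, n_starts)):
        x0 = np.zeros(K)
        x0[-1] = eta0
        if s > 0:
            x0[:-1] += rng.normal(0.0, 0.3, K - 1)
            x0[-1] += rng.normal(0.0, 0.3)
        res = minimize(
            fun,
            x0,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    params = best.x
    loglik = -best.fun
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.inf
    converged = bool(best.success or grad_norm < 1e-3)
    if not converged and grad_norm > 1.0:
        raise RuntimeError(f"POPAN fit failed to converge for {spec.name}")

    H = _numerical_hessian(fun, params)
    from .cjs import _newton_polish

    params, best_f = _newton_polish(fun, params, H)
    loglik = -best_f
    vcov = np.linalg.pinv(H)

    n_ess = int(np.sum(weights * small.x.sum(axis=1)))
    a = aicc(loglik, K, n_ess)
    q = qaicc(loglik, K, n_ess, c_hat)

    phi, phi0, p, pent, eta_N = design.probs(params)
    years = small.years
    infl = np.sqrt(max(c_hat, 1.0))

    real = {}
    real["phi"] = _logit_table(
        design, params, vcov, "phi", phi0, years[:-1], infl
    )
    real["p"] = _logit_table(design, params, vcov, "p", p, years, infl)
    real["pent"] = _pent_table(design, params, vcov, pent, years, infl)

    se_eta = float(np.sqrt(max(vcov[-1, -1], 0.0))) * infl
    N_hat = D + float(np.exp(params[-1]))
    est = SuperPopulationEstimate(
        N_hat=N_hat,
        se=float(np.exp(params[-1])) * se_eta,
        lcl=D + float(np.exp(params[-1] - 1.96 * se_eta)),
        ucl=D + float(np.exp(params[-1] + 1.96 * se_eta)),
        period=(int(years[0]), int(years[-1])),
    )
    return FitResult(
        name=spec.name,
        coefs=params,
        coef_names=design.cjs.phi_names
        + design.cjs.p_names
        + [f"pent:{i}" for i in range(design.k_pent)]
        + ["log(N-D)"],
        vcov=vcov,
        loglik=loglik,
        K=K,
        n_ess=n_ess,
        c_hat=c_hat,
        aicc=a,
        qaicc=q,
        converged=converged,
        boundary=bool(np.any(p > 1 - 1e-4) or np.any(phi0 > 1 - 1e-4)),
        real=real,
        extras={"N": est, "D": D, "grad_norm": grad_norm},
    )


def _fd_jacobian(fn, params, h=1e-5):
    base = fn(params)
    J = np.zeros((len(base), len(params)))
    for k in range(len(params)):
        dp = params.copy()
        dp[k] += h
        J[:, k] = (fn(dp) - base) / h
    return J


def _logit_table(design, params, vcov, which, est, index, infl):
    """Delta-method table on the logit scale for a per-occasion series."""

    def eta_fn(th):
        phi, phi0, p, pent, _ = design.probs(th)
        v = phi0 if which == "phi" else p
        return np.log(np.clip(v, 1e-12, 1 - 1e-12) / np.clip(1 - v, 1e-12, None))

    J = _fd_jacobian(eta_fn, params)
    var = np.einsum("jk,kl,jl->j", J, vcov, J)
    se = np.sqrt(np.clip(var, 0, None)) * infl
    eta = eta_fn(params)
    return pd.DataFrame(
        {
            "logit": eta,
            "logit_se": se,
            "est": expit(eta),
            "se": expit(eta) * (1 - expit(eta)) * se,
            "lcl": expit(eta - 1.96 * se),
            "ucl": expit(eta + 1.96 * se),
        },
        index=index,
    )


def _pent_table(design, params, vcov, pent, index, infl):
    def pent_fn(th):
        return design.probs(th)[3]

    J = _fd_jacobian(pent_fn, params)
    var = np.einsum("jk,kl,jl->j", J, vcov, J)
    se = np.sqrt(np.clip(var, 0, None)) * infl
    pc = np.clip(pent, 1e-12, 1 - 1e-12)
    eta = np.log(pc / (1 - pc))
    return pd.DataFrame(
        {
            "logit": eta,
            "logit_se": se / (pc * (1 - pc)),
            "est": pent,
            "se": se,
            "lcl": np.clip(pent - 1.96 * se, 0, 1),
            "ucl": np.clip(pent + 1.96 * se, 0, 1),
        },
        index=index,
    )


def average_superpopulation(model_set: ModelSet) -> SuperPopulationEstimate:
    """QAICc-weighted model-averaged N with unconditional SE.

    Between-model spread enters the unconditional variance
    (Burnham-Anderson); the CI is log-normal on N - D.
    """
    fits = [f for f in model_set.fits if "N" in f.extras]
    if not fits:
        raise ValueError("no fit carries a super-population estimate")
    w = akaike_weights([f.ic for f in fits])
    Ns = np.array([f.extras["N"].N_hat for f in fits])
    ses = np.array([f.extras["N"].se for f in fits])
    D = fits[0].extras["D"]
    N_bar = float(w @ Ns)
    var = float(w @ (ses**2 + (Ns - N_bar) ** 2))
    g = N_bar - D
    if g <= 0:
        return SuperPopulationEstimate(N_bar, np.sqrt(var), N_bar, N_bar, fits[0].extras["N"].period)
    C = np.exp(1.96 * np.sqrt(np.log(1.0 + var / g**2)))
    return SuperPopulationEstimate(
        N_hat=N_bar,
        se=float(np.sqrt(var)),
        lcl=D + g / C,
        ucl=D + g * C,
        period=fits[0].extras["N"].period,
    )
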