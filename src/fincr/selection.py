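"""Information criteria, Akaike weights, and model averaging.

AICc = -2 lnL + 2K + 2K(K+1)/(n - K - 1) with n the effective sample size
(total releases for capture-recapture likelihoods).  With estimated
overdispersion c-hat, QAICc divides -2 lnL by c-hat and (by the
Burnham-Anderson convention, toggleable) counts c-hat as an extra
parameter.  Model-averaged real parameters use Akaike weights with
unconditional variances that add the between-model spread; probability
series are averaged on the logit scale so the averaged CI respects (0,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["aicc", "qaicc", "akaike_weights", "ModelSet", "model_average"]


def aicc(loglik: float, K: int, n_ess: float) -> float:
    if n_ess <= K + 1:
        raise ValueError("effective sample size must exceed K + 1")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n_ess - K - 1)


def qaicc(
    loglik: float,
    K: int,
    n_ess: float,
    c_hat: float,
    count_c_hat: bool = True,
) -> float:
    """Quasi-likelihood AICc; reduces to AICc at c_hat = 1."""
    if c_hat < 1.0:
        warnings.warn("c_hat < 1 clamped to 1", stacklevel=2)
        c_hat = 1.0
    Keff = K + 1 if (count_c_hat and c_hat > 1.0) else K
    if n_ess <= Keff + 1:
        raise ValueError("effective sample size must exceed K + 1")
    return -2.0 * loglik / c_hat + 2.0 * Keff + 2.0 * Keff * (Keff + 1) / (
        n_ess - Keff - 1
    )


def akaike_weights(ic_values) -> np.ndarray:
    """w_i = exp(-delta_i / 2) normalized; invariant to a constant shift."""
    ic = np.asarray(ic_values, dtype=float)
    if ic.size == 0:
        raise ValueError("need at least one IC value")
    delta = ic - ic.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelSet:
    """A collection of fits of the same data, ranked by (Q)AICc."""

    fits: list

    def __post_init__(self):
        if not self.fits:
            raise ValueError("empty model set")
        order = np.argsort([f.ic for f in self.fits], kind="stable")
        self.fits = [self.fits[i] for i in order]

    @property
    def ic_values(self) -> np.ndarray:
        return np.array([f.ic for f in self.fits])

    @property
    def delta(self) -> np.ndarray:
        return self.ic_values - self.ic_values.min()

    @property
    def weights(self) -> np.ndarray:
        return akaike_weights(self.ic_values)

    def table(self) -> pd.DataFrame:
        """Comparison table: model, npar, IC, delta, weight, deviance."""
        rows = []
        for f, d, w in zip(self.fits, self.delta, self.weights):
            rows.append(
                {
                    "model": f.name,
                    "npar": f.K,
                    "IC": f.ic,
                    "delta": d,
                    "weight": w,
                    "deviance": f.extras.get("deviance", np.nan),
                }
            )
        return pd.DataFrame(rows)


def model_average(model_set: ModelSet, series_name: str) -> pd.DataFrame:
    """Model-averaged real-parameter series with unconditional SEs.

    Averages on the logit scale: point estimate sum(w_i eta_i);
    unconditional variance sum(w_i [var_i + (eta_i - eta_bar)^2]); CI from
    the averaged logit +- 1.96 unconditional SE, back-transformed.
    """
    fits = [f for f in model_set.fits if series_name in f.real]
    if not fits:
        raise KeyError(f"no fit exposes series {series_name!r}")
    w = akaike_weights([f.ic for f in fits])
    index = fits[0].real[series_name].index
    etas, variances = [], []
    for f in fits:
        df = f.real[series_name]
        if not df.index.equals(index):
            raise ValueError("real-parameter series have mismatched indices")
        etas.append(df["logit"].to_numpy())
        variances.append(df["logit_se"].to_numpy() ** 2)
    etas = np.vstack(etas)
    variances = np.vstack(variances)
    eta_bar = w @ etas
    uncond_var = w @ (variances + (etas - eta_bar) ** 2)
    se = np.sqrt(uncond_var)
    return pd.DataFrame(
        {
            "logit": eta_bar,
            "logit_se": se,
            "est": expit(eta_bar),
            "se": expit(eta_bar) * (1 - expit(eta_bar)) * se,
            "lcl": expit(eta_bar - 1.96 * se),
            "ucl": expit(eta_bar + 1.96 * se),
        },
        index=index,
    )
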