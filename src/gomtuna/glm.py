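"""Quasi-Poisson school-count model with backward stepwise elimination.

The response is the number of fish per school; candidate covariates are
year, day of year, latitude and longitude (all continuous) plus their six
pairwise interactions.  Fitting is log-link Poisson IRLS; quasi-Poisson
inference scales standard errors by the square root of the Pearson
dispersion and refers t statistics to a Student t with the residual degrees
of freedom, matching the conventions of R's ``glm``/``summary`` for the
``quasipoisson`` family.  Overdispersion is flagged when residual deviance
per degree of freedom exceeds 1.5.

Backward selection removes, one per refit, the least significant removable
term with p above alpha — interactions before main effects, a main effect
only once no retained interaction contains it (marginality).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MAIN_TERMS",
    "INTERACTION_TERMS",
    "CANONICAL_TERMS",
    "GlmSpec",
    "GlmFit",
    "fit_quasipoisson",
    "check_overdispersion",
    "backward_select",
]

MAIN_TERMS = ("year", "dayofyear", "latitude", "longitude")
#: All six pairwise interactions of the four main effects.
INTERACTION_TERMS = (
    "latitude:longitude",
    "latitude:dayofyear",
    "longitude:dayofyear",
    "latitude:year",
    "longitude:year",
    "dayofyear:year",
)
CANONICAL_TERMS = MAIN_TERMS + INTERACTION_TERMS

_COLUMN_OF = {
    "year": "year",
    "dayofyear": "day_of_year",
    "latitude": "latitude",
    "longitude": "longitude",
}


def _parents(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


@dataclass(frozen=True)
class GlmSpec:
    """Model terms (intercept implicit); must respect marginality."""

    terms: tuple = CANONICAL_TERMS

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        unknown = [t for t in self.terms if t not in CANONICAL_TERMS]
        if unknown:
            raise ValueError(f"unknown terms: {unknown}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms")
        for t in self.interactions:
            missing = [p for p in _parents(t) if p not in self.terms]
            if missing:
                raise ValueError(f"interaction {t} lacks main effect(s) {missing}")

    @property
    def interactions(self) -> tuple:
        return tuple(t for t in self.terms if ":" in t)

    @property
    def mains(self) -> tuple:
        return tuple(t for t in self.terms if ":" not in t)

    def without(self, term: str) -> "GlmSpec":
        return GlmSpec(tuple(t for t in self.terms if t != term))

    def ordered(self) -> tuple:
        return tuple(t for t in CANONICAL_TERMS if t in self.terms)


@dataclass
class GlmFit:
    """Coefficients and quasi-Poisson inference for one fitted model."""

    terms: tuple                  # model terms (intercept excluded)
    coef: dict                    # term -> estimate, incl. "Intercept"
    se: dict                      # quasi-Poisson standard errors
    tvalues: dict
    pvalues: dict                 # two-sided, t with residual df
    dispersion: float             # Pearson chi-square / residual df
    deviance: float
    df_resid: int
    nobs: int
    converged: bool
    n_iter: int
    deviance_trace: list = field(default_factory=list)
    elimination_log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        order = ("Intercept",) + tuple(self.terms)
        return {
            "terms": list(self.terms),
            "coefficients": {t: self.coef[t] for t in order},
            "standard_errors": {t: self.se[t] for t in order},
            "t_values": {t: self.tvalues[t] for t in order},
            "p_values": {t: self.pvalues[t] for t in order},
            "dispersion": self.dispersion,
            "deviance": self.deviance,
            "df_resid": self.df_resid,
            "nobs": self.nobs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "elimination_log": [
                {"step": s, "removed": t, "p_value": p} for s, t, p in self.elimination_log
            ],
        }


def design_matrix(df: pd.DataFrame, spec: GlmSpec):
    """Raw design matrix (intercept first) and column names."""
    names = ["Intercept"] + list(spec.ordered())
    cols = [np.ones(len(df))]
    base = {m: df[_COLUMN_OF[m]].to_numpy(float) for m in MAIN_TERMS}
    for t in spec.ordered():
        parts = _parents(t)
        col = base[parts[0]].copy()
        for p in parts[1:]:
            col = col * base[p]
        cols.append(col)
    return np.column_stack(cols), names


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


class ConvergenceError(RuntimeError):
    pass


def fit_quasipoisson(df: pd.DataFrame, spec: GlmSpec = GlmSpec(),
                     tol: float = 1e-8, max_iter: int = 100) -> GlmFit:
    """Fit the count model by IRLS with quasi-Poisson inference.

    Covariate columns are standardized internally for conditioning and the
    coefficients mapped back to the original scale; fitted means (and hence
    deviance, dispersion and non-intercept t statistics) are unchanged by
    this reparameterization.
    """
    y = df["n_fish"].to_numpy(float)
    X_raw, names = design_matrix(df, spec)
    n, p = X_raw.shape
    if n <= p:
        raise ValueError(f"need more than {p} observations to fit {p} coefficients")

    means = X_raw.mean(axis=0)
    sds = X_raw.std(axis=0, ddof=1)
    means[0], sds[0] = 0.0, 1.0  # leave the intercept column alone
    if np.any(sds == 0.0):
        bad = [names[j] for j in range(1, p) if sds[j] == 0.0]
        raise ValueError(f"constant design column(s): {bad}")
    Xs = (X_raw - means) / sds

    rank = np.linalg.matrix_rank(Xs)
    if rank < p:
        _, _, vt = np.linalg.svd(Xs)
        null = np.abs(vt[-1])
        bad = [names[j] for j in np.nonzero(null > 0.1)[0]]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")

    mu = y + 0.1
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    trace = [dev]
    converged = False
    beta = np.zeros(p)
    for it in range(1, max_iter + 1):
        w = mu
        z = eta + (y - mu) / mu
        xtw = Xs.T * w
        beta = np.linalg.solve(xtw @ Xs, xtw @ z)
        eta = np.clip(Xs @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        new_dev = _poisson_deviance(y, mu)
        trace.append(new_dev)
        if abs(new_dev - dev) / (abs(dev) + 0.1) < tol:
            converged = True
            dev = new_dev
            break
        dev = new_dev
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations; deviance trace: {trace}")

    df_resid = n - p
    pearson = float(np.sum((y - mu) ** 2 / mu))
    phi = pearson / df_resid
    cov_s = phi * np.linalg.inv((Xs.T * mu) @ Xs)

    # back-transform: column j standardized as (x - m_j)/s_j
    beta_raw = beta / sds
    a0 = np.concatenate(([1.0], -means[1:] / sds[1:]))
    beta_raw[0] = a0 @ beta
    se_raw = np.sqrt(np.diag(cov_s)) / sds
    se_raw[0] = float(np.sqrt(a0 @ cov_s @ a0))

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta_raw / se_raw
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return GlmFit(
        terms=tuple(names[1:]),
        coef=dict(zip(names, beta_raw)),
        se=dict(zip(names, se_raw)),
        tvalues=dict(zip(names, tvals)),
        pvalues=dict(zip(names, pvals)),
        dispersion=phi,
        deviance=dev,
        df_resid=df_resid,
        nobs=n,
        converged=converged,
        n_iter=it,
        deviance_trace=trace,
    )


def check_overdispersion(fit: GlmFit) -> bool:
    """True iff residual deviance per residual df strictly exceeds 1.5."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    return fit.deviance / fit.df_resid > 1.5


def backward_select(df: pd.DataFrame, full_spec: GlmSpec = GlmSpec(),
                    alpha: float = 0.05, **fit_kwargs) -> GlmFit:
    """Backward stepwise elimination at level ``alpha``.

    Each round refits the model, then removes the removable term with the
    largest p-value above alpha (ties broken toward the later term in the
    canonical ordering); interactions go before main effects, and a main
    effect is never removed while a retained interaction contains it.
    """
    spec = full_spec
    log: list = []
    step = 0
    order = {t: i for i, t in enumerate(CANONICAL_TERMS)}
    while True:
        fit = fit_quasipoisson(df, spec, **fit_kwargs) if spec.terms else _intercept_only(df)
        # weak interactions first; free mains only once no interaction is weak
        weak = [(t, fit.pvalues[t]) for t in spec.interactions if fit.pvalues[t] > alpha]
        if not weak:
            free = [
                m for m in spec.mains
                if not any(m in _parents(t) for t in spec.interactions)
            ]
            weak = [(m, fit.pvalues[m]) for m in free if fit.pvalues[m] > alpha]
        if not weak:
            fit.elimination_log = log
            return fit
        weak.sort(key=lambda tp: (tp[1], order[tp[0]]))  # largest p last; later term wins ties
        term, pval = weak[-1]
        step += 1
        log.append((step, term, float(pval)))
        spec = spec.without(term)


def _intercept_only(df: pd.DataFrame) -> GlmFit:
    """Closed-form intercept-only quasi-Poisson fit (MLE is the sample mean)."""
    y = df["n_fish"].to_numpy(float)
    n = len(y)
    mu = float(y.mean())
    dev = _poisson_deviance(y, np.full(n, mu))
    df_resid = n - 1
    phi = float(np.sum((y - mu) ** 2 / mu)) / df_resid
    se = float(np.sqrt(phi / (n * mu)))
    b0 = float(np.log(mu))
    tval = b0 / se
    return GlmFit(
        terms=(),
        coef={"Intercept": b0},
        se={"Intercept": se},
        tvalues={"Intercept": tval},
        pvalues={"Intercept": float(2.0 * stats.t.sf(abs(tval), df_resid))},
        dispersion=phi,
        deviance=dev,
        df_resid=df_resid,
        nobs=n,
        converged=True,
        n_iter=0,
    )
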