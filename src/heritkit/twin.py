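"""Classical twin-design heritability: correlations, ACE maximum likelihood,
and the Falconer moment estimator.

The ACE decomposition writes the phenotypic variance as additive genetic
(A), shared environmental (C) and unique environmental (E) parts.  MZ
co-twins share A fully and DZ co-twins half of it, so the model-implied
twin correlations are ``rMZ = a2 + c2`` and ``rDZ = a2/2 + c2`` (lowercase
denoting standardized components).  Fitting is direct maximum likelihood on
the 2x2 exchangeable bivariate-normal covariance structures — an estimand
equivalent to the usual path-model formulation but verifiable against
closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datatypes import HeritkitError, TwinDataset

__all__ = ["twin_correlations", "fit_ace", "falconer", "TwinFit"]


def _double_entry_r(pairs: np.ndarray) -> float:
    """Intraclass correlation via the double-entry (pair-symmetrized) Pearson
    estimator: correlate the stacked (x1, x2) and (x2, x1) columns."""
    if pairs.shape[0] < 2:
        raise HeritkitError("need at least 2 pairs per zygosity group")
    a = np.concatenate([pairs[:, 0], pairs[:, 1]])
    b = np.concatenate([pairs[:, 1], pairs[:, 0]])
    if a.std() == 0:
        raise HeritkitError("zero phenotype variance in a zygosity group")
    return float(np.corrcoef(a, b)[0, 1])


def _anova_icc(pairs: np.ndarray) -> float:
    """One-way ANOVA intraclass correlation (alternative estimator)."""
    k = 2
    grand = pairs.mean()
    msb = k * ((pairs.mean(axis=1) - grand) ** 2).sum() / (pairs.shape[0] - 1)
    msw = ((pairs - pairs.mean(axis=1, keepdims=True)) ** 2).sum() / pairs.shape[0]
    return float((msb - msw) / (msb + (k - 1) * msw))


def twin_correlations(data: TwinDataset, method: str = "double-entry"
                      ) -> tuple[float, float]:
    """MZ and DZ intraclass correlations (double-entry Pearson by default,
    ``method='anova'`` for the one-way ANOVA ICC)."""
    est = {"double-entry": _double_entry_r, "anova": _anova_icc}[method]
    return est(data.mz), est(data.dz)


@dataclass
class TwinFit:
    """Standardized ACE estimates with implied correlations and submodels."""

    a2: float
    c2: float
    e2: float
    mean: float
    total_variance: float
    minus2_loglik: float
    converged: bool
    ci: dict[str, tuple[float, float]]            # delta-method 95% intervals
    submodels: dict[str, "TwinFit"]               # AE, CE, E
    submodel_tests: dict[str, tuple[float, float]]  # name -> (LR stat, p)

    @property
    def r_mz(self) -> float:
        return self.a2 + self.c2

    @property
    def r_dz(self) -> float:
        return 0.5 * self.a2 + self.c2


def _pair_loglik(pairs: np.ndarray, mean: float, variance: float, r: float) -> float:
    """Summed log-density of exchangeable bivariate-normal pairs."""
    if not np.isfinite(variance) or not 0 < variance < 1e100 or not -1 < r < 1:
        return -np.inf
    z = pairs - mean
    det = variance**2 * (1 - r**2)
    quad = (z[:, 0] ** 2 + z[:, 1] ** 2 - 2 * r * z[:, 0] * z[:, 1]) / (
        variance * (1 - r**2)
    )
    return float(-0.5 * (pairs.shape[0] * (np.log(det) + 2 * np.log(2 * np.pi)) + quad.sum()))


_R_EPS = 1e-8  # keeps the bivariate-normal determinant positive


def _neg_loglik_corr(params: np.ndarray, data: TwinDataset, model: str) -> float:
    """Negative log-likelihood in the (mean, log variance, correlations)
    parameterization, where the likelihood factorizes over zygosity.

    ``model`` fixes the submodel: ACE has free (rMZ, rDZ); AE constrains
    rDZ = rMZ / 2; CE constrains rDZ = rMZ; E has both correlations 0.
    """
    mean, logv = params[0], params[1]
    v = np.exp(min(logv, 200.0))  # cap keeps exploratory steps finite
    if model == "ACE":
        r_mz, r_dz = params[2], params[3]
    elif model == "AE":
        r_mz, r_dz = params[2], 0.5 * params[2]
    elif model == "CE":
        r_mz = r_dz = params[2]
    else:  # E
        r_mz = r_dz = 0.0
    ll = _pair_loglik(data.mz, mean, v, r_mz)
    ll += _pair_loglik(data.dz, mean, v, r_dz)
    return -ll


def _fit_submodel(data: TwinDataset, model: str) -> tuple:
    """Maximize the twin likelihood; returns (mean, comps, -2logL, ok).

    The ACE wedge ``rMZ/2 <= rDZ <= rMZ <= 1`` (i.e. a2, c2, e2 >= 0) enters
    as linear constraints on the correlation parameters, so the degenerate
    e2 -> 0 ridge poses no split ambiguity between a2 and c2.
    """
    both = np.concatenate([data.mz.ravel(), data.dz.ravel()])
    m0, v0 = both.mean(), both.var()
    r_mz0 = min(max(_double_entry_r(data.mz), 0.01), 1 - 1e-4)
    r_dz0 = min(max(_double_entry_r(data.dz), r_mz0 / 2), r_mz0)
    if model == "ACE":
        x0 = np.array([m0, np.log(v0), r_mz0, r_dz0])
        constraints = [
            {"type": "ineq", "fun": lambda p: p[2] - p[3]},          # a2 >= 0
            {"type": "ineq", "fun": lambda p: 2 * p[3] - p[2]},      # c2 >= 0
            {"type": "ineq", "fun": lambda p: 1 - _R_EPS - p[2]},    # e2 >= 0
            {"type": "ineq", "fun": lambda p: p[3]},                 # rDZ >= 0
        ]
    elif model in ("AE", "CE"):
        x0 = np.array([m0, np.log(v0), r_mz0])
        constraints = [
            {"type": "ineq", "fun": lambda p: p[2]},
            {"type": "ineq", "fun": lambda p: 1 - _R_EPS - p[2]},
        ]
    else:
        x0 = np.array([m0, np.log(v0)])
        constraints = []
    res = optimize.minimize(
        _neg_loglik_corr, x0, args=(data, model), method="SLSQP",
        constraints=constraints, options={"maxiter": 500, "ftol": 1e-12},
    )
    mean, v = res.x[0], float(np.exp(res.x[1]))
    if model == "ACE":
        r_mz, r_dz = res.x[2], res.x[3]
    elif model == "AE":
        r_mz, r_dz = res.x[2], 0.5 * res.x[2]
    elif model == "CE":
        r_mz = r_dz = res.x[2]
    else:
        r_mz = r_dz = 0.0
    comps = v * np.clip(
        [2 * (r_mz - r_dz), 2 * r_dz - r_mz, 1 - r_mz], 0.0, None
    )
    return mean, comps, 2.0 * res.fun, res.success, res


def fit_ace(data: TwinDataset) -> TwinFit:
    """Maximum-likelihood ACE fit with nested AE/CE/E submodel comparisons.

    Components are constrained nonnegative; estimates are reported on the
    standardized scale (a2 + c2 + e2 = 1).  Confidence intervals are
    delta-method Wald intervals from a numerical Hessian.  An optimizer
    failure is flagged on the result, not raised.
    """
    if data.n_mz < 2 or data.n_dz < 2:
        raise HeritkitError("both zygosity groups need at least 2 pairs")
    mean, comps, m2ll, ok, res = _fit_submodel(data, "ACE")
    total = comps.sum()
    a2, c2, e2 = comps / total

    ci = _wald_ci(data, mean, comps)

    submodels: dict[str, TwinFit] = {}
    tests: dict[str, tuple[float, float]] = {}
    for name, df in (("AE", 1), ("CE", 1), ("E", 2)):
        s_mean, s_comps, s_m2ll, s_ok, _ = _fit_submodel(data, name)
        s_total = s_comps.sum()
        sub = TwinFit(
            a2=s_comps[0] / s_total, c2=s_comps[1] / s_total,
            e2=s_comps[2] / s_total, mean=s_mean, total_variance=s_total,
            minus2_loglik=s_m2ll, converged=s_ok, ci={}, submodels={},
            submodel_tests={},
        )
        stat = max(s_m2ll - m2ll, 0.0)
        tests[name] = (stat, float(stats.chi2.sf(stat, df=df)))
        submodels[name] = sub

    return TwinFit(
        a2=float(a2), c2=float(c2), e2=float(e2), mean=float(mean),
        total_variance=float(total), minus2_loglik=float(m2ll),
        converged=bool(ok), ci=ci, submodels=submodels, submodel_tests=tests,
    )


def _wald_ci(data: TwinDataset, mean: float, comps: np.ndarray,
             level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Delta-method intervals for the standardized components from a
    finite-difference Hessian of the unstandardized likelihood."""
    params = np.concatenate([[mean], np.maximum(comps, 1e-6)])

    def nll(p):
        m, a, c, e = p
        total = a + c + e
        if e <= 0 or total <= 0:
            return np.inf
        ll = _pair_loglik(data.mz, m, total, (a + c) / total)
        ll += _pair_loglik(data.dz, m, total, (0.5 * a + c) / total)
        return -ll

    eps = 1e-4 * max(1.0, comps.sum())
    k = len(params)
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = params.copy(); pp[i] += eps; pp[j] += eps; fpp = nll(pp)
            pm = params.copy(); pm[i] += eps; pm[j] -= eps; fpm = nll(pm)
            mp = params.copy(); mp[i] -= eps; mp[j] += eps; fmp = nll(mp)
            mm = params.copy(); mm[i] -= eps; mm[j] -= eps; fmm = nll(mm)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    total = comps.sum()
    z = stats.norm.ppf(0.5 + level / 2)
    out: dict[str, tuple[float, float]] = {}
    for idx, name in ((1, "a2"), (2, "c2"), (3, "e2")):
        grad = np.zeros(k)
        for j in (1, 2, 3):
            grad[j] = (1.0 if j == idx else 0.0) / total - comps[idx - 1] / total**2
        var = float(grad @ cov @ grad)
        se = np.sqrt(max(var, 0.0))
        est = comps[idx - 1] / total
        out[name] = (max(est - z * se, 0.0), min(est + z * se, 1.0))
    return out


def falconer(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Falconer moment estimates ``(a2, c2, e2)`` from twin correlations.

    ``a2 = 2 (rMZ - rDZ)``, ``c2 = 2 rDZ - rMZ``, ``e2 = 1 - rMZ``; raw
    moments, deliberately untruncated (values can exit [0, 1]).
    """
    for name, r in (("rMZ", r_mz), ("rDZ", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise HeritkitError(f"{name} must lie in [-1, 1]")
    return 2.0 * (r_mz - r_dz), 2.0 * r_dz - r_mz, 1.0 - r_mz
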