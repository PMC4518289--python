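"""Variance-component estimation by restricted maximum likelihood (REML).

The model is the standard GRM mixed model

    y = X b + sum_c g_c + e,        V = sum_c G_c sigma2_c + I sigma2_e,

where each ``G_c`` is a genetic relationship matrix and the implicit
residual component has identity covariance.  The restricted log-likelihood
is used throughout in the convention

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

i.e. the constant ``-(n - p)/2 log(2 pi)`` (and the fixed ``+1/2 log|X'X|``
of the error-contrast formulation) is dropped; likelihood *differences* are
unaffected.

Fitting uses average-information (AI) updates with an EM-REML warm-up for
stability, variance components constrained nonnegative by projection onto a
small positive floor; a component that keeps sticking to the floor is fixed
there (reported as 0 with a boundary flag).  Standard errors come from the
inverse AI matrix at the optimum, proportions (per-component h2) by the
delta method.  For a single genetic component the fit runs in the
eigenbasis of ``G``, where ``V`` is diagonal and every update is O(n p^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

from .datatypes import GenotypeMatrix, GRMResult, HeritkitError
from .grm import compute_grm, grm_pca

__all__ = [
    "MixedModelSpec",
    "VarianceComponentsFit",
    "LRTResult",
    "reml_loglik",
    "reml_fit",
    "lrt",
    "estimate_h2",
    "H2Report",
]

_FLOOR_FRAC = 1e-6  # boundary floor as a fraction of var(y), GCTA-style


@dataclass
class MixedModelSpec:
    """Phenotype, fixed-effects design, and named GRM components."""

    y: np.ndarray
    X: np.ndarray
    components: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise HeritkitError("X rows must match phenotype length")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise HeritkitError("fixed-effects design X is rank deficient")
        for name, g in self.components:
            g = np.asarray(g, dtype=float)
            if g.shape != (n, n):
                raise HeritkitError(f"GRM {name!r} shape {g.shape} != ({n}, {n})")
            if not np.allclose(g, g.T, atol=1e-10):
                raise HeritkitError(f"GRM {name!r} not symmetric")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class VarianceComponentsFit:
    """AI-REML result: variance components, SEs, proportions, diagnostics."""

    names: list[str]                  # genetic components then "residual"
    sigma2: np.ndarray
    se: np.ndarray
    proportions: np.ndarray           # sigma2_c / total for every component
    proportion_se: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    boundary: np.ndarray              # True where pinned at the zero floor
    n: int
    ai: np.ndarray = field(repr=False, default=None)

    @property
    def h2(self) -> float:
        """Total genetic proportion (sum over non-residual components)."""
        return float(self.proportions[:-1].sum())

    @property
    def h2_se(self) -> float:
        """Delta-method SE of the total genetic proportion."""
        if self.ai is None:
            return float("nan")
        cov = _safe_inv(self.ai)
        total = self.sigma2.sum()
        grad = np.full(len(self.sigma2), -self.sigma2[:-1].sum() / total**2)
        grad[:-1] += 1.0 / total
        return float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": self.names,
            "sigma2": self.sigma2,
            "se": self.se,
            "prop": self.proportions,
            "prop_se": self.proportion_se,
        })


@dataclass
class LRTResult:
    statistic: float
    df_dropped: int
    p_value: float


# ---------------------------------------------------------------------------
# likelihood engines
# ---------------------------------------------------------------------------

class _DenseEngine:
    """Generic dense-V engine for any number of components."""

    def __init__(self, spec: MixedModelSpec):
        self.y, self.X = spec.y, spec.X
        self.gs = [np.asarray(g, dtype=float) for _, g in spec.components]
        self.n = spec.n

    def evaluate(self, var: np.ndarray, need_derivs: bool = True):
        n = self.n
        v = var[-1] * np.eye(n)
        for s2, g in zip(var[:-1], self.gs):
            v += s2 * g
        try:
            cho = sla.cho_factor(v, lower=True)
        except np.linalg.LinAlgError as exc:
            raise HeritkitError(
                "V singular at the evaluation point; add jitter or constrain "
                f"components ({exc})"
            ) from exc
        logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
        vinv = sla.cho_solve(cho, np.eye(n))
        w = vinv @ self.X
        xtvx = self.X.T @ w
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            raise HeritkitError("X'V^-1X not positive definite")
        cinv = np.linalg.inv(xtvx)
        py = vinv @ self.y - w @ (cinv @ (w.T @ self.y))
        ypy = self.y @ py
        loglik = -0.5 * (logdet_v + logdet_x + ypy)
        if not need_derivs:
            return loglik, None, None
        mats = self.gs + [None]  # None stands for the identity
        k = len(mats)
        us, pus, traces, quads = [], [], [], []
        for g in mats:
            u = py if g is None else g @ py
            tr_vg = np.trace(vinv) if g is None else float((vinv * g).sum())
            b = w if g is None else g @ w
            t = tr_vg - float((cinv * (w.T @ b)).sum())
            pu = vinv @ u - w @ (cinv @ (w.T @ u))
            us.append(u)
            pus.append(pu)
            traces.append(t)
            quads.append(float(py @ u))
        score = 0.5 * (np.array(quads) - np.array(traces))
        ai = 0.5 * np.array([[us[i] @ pus[j] for j in range(k)] for i in range(k)])
        ai = (ai + ai.T) / 2.0
        return loglik, score, ai


class _EigenEngine:
    """Single-genetic-component engine in the eigenbasis of G (V diagonal)."""

    def __init__(self, spec: MixedModelSpec):
        g = np.asarray(spec.components[0][1], dtype=float)
        self.lam, u = np.linalg.eigh(g)
        self.yt = u.T @ spec.y
        self.xt = u.T @ spec.X
        self.n = spec.n

    def evaluate(self, var: np.ndarray, need_derivs: bool = True):
        sg, se = var
        d = sg * self.lam + se
        if (d <= 0).any():
            raise HeritkitError("V singular at the evaluation point (nonpositive eigenvalue)")
        dinv = 1.0 / d
        logdet_v = float(np.log(d).sum())
        w = dinv[:, None] * self.xt
        xtvx = self.xt.T @ w
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            raise HeritkitError("X'V^-1X not positive definite")
        cinv = np.linalg.inv(xtvx)
        py = dinv * self.yt - w @ (cinv @ (w.T @ self.yt))
        loglik = -0.5 * (logdet_v + logdet_x + float(self.yt @ py))
        if not need_derivs:
            return loglik, None, None
        us = [self.lam * py, py]
        traces = [
            float((self.lam * dinv).sum()) - float((cinv * (w.T @ (self.lam[:, None] * w))).sum()),
            float(dinv.sum()) - float((cinv * (w.T @ w)).sum()),
        ]
        quads = [float(py @ u) for u in us]
        pus = [dinv * u - w @ (cinv @ (w.T @ u)) for u in us]
        score = 0.5 * (np.array(quads) - np.array(traces))
        ai = 0.5 * np.array([[us[i] @ pus[j] for j in range(2)] for i in range(2)])
        ai = (ai + ai.T) / 2.0
        return loglik, score, ai


def _engine(spec: MixedModelSpec):
    return _EigenEngine(spec) if spec.n_components == 1 else _DenseEngine(spec)


def _safe_inv(a: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(a)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(a)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def reml_loglik(spec: MixedModelSpec, variances) -> float:
    """Restricted log-likelihood at fixed variance components.

    ``variances`` lists the genetic components in spec order followed by the
    residual.  Convention: ``-1/2 [log|V| + log|X'V^-1X| + y'Py]``.
    """
    var = np.asarray(variances, dtype=float)
    if len(var) != spec.n_components + 1:
        raise HeritkitError("need one variance per component plus the residual")
    if (var < 0).any():
        raise HeritkitError("variances must be nonnegative")
    loglik, _, _ = _DenseEngine(spec).evaluate(var, need_derivs=False)
    return float(loglik)


def reml_fit(spec: MixedModelSpec, init: np.ndarray | None = None,
             tol: float = 1e-8, max_iter: int = 100,
             em_iters: int = 2) -> VarianceComponentsFit:
    """Fit the variance components by AI-REML with EM warm-up.

    The first ``em_iters`` updates are EM-REML; subsequent iterations take
    average-information steps (falling back to EM whenever an AI step would
    lower the likelihood or leave the feasible region entirely).  Components
    are kept nonnegative by projection to a small floor; a component pinned
    there for three consecutive iterations is fixed at the boundary.
    Non-convergence is reported in the ``converged`` flag, not raised.
    """
    k = spec.n_components + 1
    vp = float(np.var(spec.y))
    if vp <= 0:
        raise HeritkitError("phenotype has zero variance")
    floor = _FLOOR_FRAC * vp
    if init is None:
        var = np.empty(k)
        var[:-1] = vp / (2.0 * max(spec.n_components, 1))
        var[-1] = vp / 2.0
    else:
        var = np.asarray(init, dtype=float).copy()
        if len(var) != k:
            raise HeritkitError("init length must equal #components + 1")
    eng = _engine(spec)
    pinned = np.zeros(k, dtype=bool)
    pin_count = np.zeros(k, dtype=int)
    loglik, score, ai = eng.evaluate(var)
    converged = False
    iteration = 0
    def _project(cand: np.ndarray) -> np.ndarray:
        cand = np.maximum(cand, floor)
        cand[pinned] = floor
        return cand

    def _try(cand: np.ndarray):
        try:
            return eng.evaluate(cand)
        except HeritkitError:
            return None

    for iteration in range(1, max_iter + 1):
        em_new = _project(var + var**2 * (2.0 * score) / spec.n)  # EM-REML
        if iteration <= em_iters:
            result = _try(em_new) or (loglik, score, ai)
            new, (new_ll, new_score, new_ai) = em_new, result
        else:
            free = ~pinned
            try:
                delta = np.linalg.solve(ai[np.ix_(free, free)], score[free])
            except np.linalg.LinAlgError:
                delta = None
            accepted = None
            if delta is not None:
                # AI step with step-halving until the likelihood improves
                step = 1.0
                for _ in range(12):
                    cand = var.copy()
                    cand[free] = var[free] + step * delta
                    cand = _project(cand)
                    result = _try(cand)
                    if result is not None and result[0] >= loglik - 1e-12:
                        accepted = (cand, result)
                        break
                    step *= 0.5
            if accepted is None:
                result = _try(em_new)
                accepted = (em_new, result) if result is not None else (var, (loglik, score, ai))
            new, (new_ll, new_score, new_ai) = accepted
        at_floor = new <= floor * (1 + 1e-9)
        pin_count = np.where(at_floor, pin_count + 1, 0)
        pinned |= (pin_count >= 3) & at_floor
        pinned[-1] = False  # the residual is never pinned
        done = abs(new_ll - loglik) < tol and iteration > em_iters
        var, loglik, score, ai = new, new_ll, new_score, new_ai
        if done:
            converged = True
            break

    cov = _safe_inv(ai)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    reported = var.copy()
    at_floor = reported <= floor * (1 + 1e-9)
    reported[at_floor & (np.arange(k) < k - 1)] = 0.0
    if (reported != var).any():
        # report the likelihood with floored genetic components at exactly 0,
        # so a boundary fit never scores below its own nested submodel
        loglik, _, _ = eng.evaluate(reported, need_derivs=False)
    total = reported.sum()
    props = reported / total
    prop_se = np.empty(k)
    for c in range(k):
        grad = np.full(k, -reported[c] / total**2)
        grad[c] += 1.0 / total
        prop_se[c] = np.sqrt(max(grad @ cov @ grad, 0.0))
    names = [name for name, _ in spec.components] + ["residual"]
    return VarianceComponentsFit(
        names=names, sigma2=reported, se=se, proportions=props,
        proportion_se=prop_se, loglik=float(loglik), iterations=iteration,
        converged=converged, boundary=at_floor[: k], n=spec.n, ai=ai,
    )


def lrt(full: VarianceComponentsFit, reduced: VarianceComponentsFit,
        mixture: bool = True) -> LRTResult:
    """Likelihood-ratio test of nested variance-component models.

    For one dropped component the null distribution is the boundary mixture
    ``1/2 chi2_0 + 1/2 chi2_1`` (``mixture=False`` gives plain chi2_1); for
    q > 1 dropped components a conservative ``chi2_q`` is used with a
    warning.
    """
    df = len(full.names) - len(reduced.names)
    if df < 1:
        raise HeritkitError("reduced model must drop at least one component")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise HeritkitError(
            f"reduced log-likelihood exceeds full by {-stat / 2:.3g}: fit failure"
        )
    stat = max(stat, 0.0)
    if df == 1:
        if mixture:
            p = 0.5 * float(stats.chi2.sf(stat, df=1)) if stat > 0 else 0.5
        else:
            p = float(stats.chi2.sf(stat, df=1))
    else:
        warnings.warn(
            f"dropping {df} variance components: using conservative chi2_{df} null",
            stacklevel=2,
        )
        p = float(stats.chi2.sf(stat, df=df))
    return LRTResult(statistic=float(stat), df_dropped=df, p_value=p)


@dataclass
class H2Report:
    """Full fit plus per-component reduced-model likelihood-ratio tests."""

    fit: VarianceComponentsFit
    reduced: dict[str, VarianceComponentsFit]
    tests: dict[str, LRTResult]

    def to_frame(self) -> pd.DataFrame:
        frame = self.fit.to_frame()
        frame["loglik"] = self.fit.loglik
        frame["lrt"] = [
            self.tests[name].statistic if name in self.tests else np.nan
            for name in self.fit.names
        ]
        frame["p"] = [
            self.tests[name].p_value if name in self.tests else np.nan
            for name in self.fit.names
        ]
        return frame


def estimate_h2(genotypes: GenotypeMatrix, phenotype: np.ndarray,
                covariates: np.ndarray | pd.DataFrame | None = None,
                partition: dict[str, set[str]] | None = None,
                n_pcs: int = 10, grm: GRMResult | None = None,
                mixture: bool = True, **fit_kwargs) -> H2Report:
    """End-to-end SNP-heritability estimate for one phenotype.

    Builds one GRM per partition category (or a single all-SNP GRM), appends
    the top ``n_pcs`` eigenvectors of the all-SNP GRM to the fixed-effects
    design, fits the full model, then refits with each genetic component
    dropped in turn and reports the boundary-mixture likelihood-ratio test.
    """
    y = np.asarray(phenotype, dtype=float).ravel()
    if len(y) != genotypes.n_subjects:
        raise HeritkitError("phenotype length must match genotype subjects")
    total_grm = grm if grm is not None else compute_grm(genotypes)
    design = [np.ones((len(y), 1))]
    if covariates is not None:
        cov = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) \
            else np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        design.append(cov)
    if n_pcs > 0:
        vecs, _ = grm_pca(total_grm, k=n_pcs)
        design.append(vecs)
    x = np.hstack(design)

    if partition is None:
        components = [("genetic", total_grm.values)]
    else:
        components = []
        snp_ids = genotypes.snp_map["snp"].to_numpy()
        for cat, snps in partition.items():
            idx = np.flatnonzero(np.isin(snp_ids, list(snps)))
            if idx.size == 0:
                raise HeritkitError(f"partition category {cat!r} matches no SNPs")
            components.append((cat, compute_grm(genotypes.subset(snps=idx)).values))

    spec = MixedModelSpec(y=y, X=x, components=components)
    fit = reml_fit(spec, **fit_kwargs)
    reduced_fits: dict[str, VarianceComponentsFit] = {}
    tests: dict[str, LRTResult] = {}
    for name, _ in components:
        keep = [(nm, g) for nm, g in components if nm != name]
        red = reml_fit(MixedModelSpec(y=y, X=x, components=keep), **fit_kwargs)
        reduced_fits[name] = red
        tests[name] = lrt(fit, red, mixture=mixture)
    return H2Report(fit=fit, reduced=reduced_fits, tests=tests)
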