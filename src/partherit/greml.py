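"""Average-information REML for multi-component variance models.

Fits y ~ N(X beta, V) with V = sum_k sigma2_k A_k + sigma2_e I, where the
A_k are genomic relatedness matrices over disjoint SNP partitions.  The
residual maximum likelihood is maximised with one expectation-maximisation
step followed by average-information (AI) Newton updates, step-halving on
likelihood decreases, and components constrained at a small positive
floor — the standard GCTA-style scheme.  Sampling covariance of the
estimates is the inverse AI matrix at convergence; heritability shares
sigma2_k / sum(sigma2) carry delta-method standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .errors import NonIdentifiableError
from .relatedness import GRM

__all__ = ["VarianceComponentModel", "GremlFit", "fit_greml", "lrt_component",
           "covariate_design", "partitioned_greml", "genetic_share"]


@dataclass
class VarianceComponentModel:
    """GRMs, fixed-effect design and phenotype sharing one sample order."""

    grms: list
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != n:
            raise ValueError("X rows must match phenotype length")
        if self.X.shape[1] >= n:
            raise ValueError("more covariates than samples")
        ids = None
        for g in self.grms:
            if g.matrix.shape[0] != n:
                raise ValueError("GRM dimension does not match phenotype")
            if ids is not None and list(g.sample_ids) != ids:
                raise ValueError("GRMs have inconsistent sample orders")
            ids = list(g.sample_ids)

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class GremlFit:
    """Converged (or diagnosed) REML fit."""

    sigma2: np.ndarray          # K genetic components then sigma2_e
    cov_sigma2: np.ndarray      # inverse AI at convergence
    loglik: float               # REML log-likelihood (constant dropped)
    h2: np.ndarray              # sigma2 / total, length K+1 (error share last)
    h2_se: np.ndarray           # delta-method SEs of the shares
    converged: bool
    n_iter: int
    floored: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    message: str = ""
    ll_path: list = field(default_factory=list)

    @property
    def sigma2_se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_sigma2), 0.0, None))


def _reml_pieces(V: np.ndarray, X: np.ndarray, y: np.ndarray):
    c, low = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    vinv = cho_solve((c, low), np.eye(V.shape[0]))
    vinv_x = vinv @ X
    xtvx = X.T @ vinv_x
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    p = vinv - vinv_x @ np.linalg.solve(xtvx, vinv_x.T)
    py = p @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ py))
    return p, py, ll


def fit_greml(
    model: VarianceComponentModel,
    max_iter: int = 100,
    tol: float = 1e-4,
    floor_frac: float = 1e-6,
) -> GremlFit:
    """Constrained AI-REML fit of the variance-component model.

    Parameters
    ----------
    model
        GRMs (possibly none, for a covariate-only model), design matrix
        with intercept, and phenotype.
    max_iter, tol
        Iteration cap and the convergence tolerance on the change in REML
        log-likelihood.
    floor_frac
        Components are constrained at ``floor_frac * var(y)``.

    Raises
    ------
    NonIdentifiableError
        If the AI matrix is singular to working precision, e.g. a GRM
        proportional to the identity and therefore confounded with the
        residual component.
    """
    n = model.n
    if n < 30:
        raise ValueError("GREML requires n >= 30")
    y, X = model.y, model.X
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    floor = floor_frac * vary

    a_mats = [0.5 * (g.matrix + g.matrix.T) for g in model.grms]
    K = len(a_mats)
    sigma = np.full(K + 1, vary / (K + 1))

    def build_v(s):
        v = s[K] * np.eye(n)
        for k in range(K):
            v += s[k] * a_mats[k]
        return v

    p, py, ll = _reml_pieces(build_v(sigma), X, y)
    ll_path = [ll]
    converged = False
    message = ""
    n_iter = 0
    ai = None
    for it in range(1, max_iter + 1):
        n_iter = it
        # gradients: score_k = -0.5 [tr(P A_k) - y'P A_k P y]
        q = np.empty((n, K + 1))
        score = np.empty(K + 1)
        for k in range(K):
            q[:, k] = a_mats[k] @ py
            tr_pa = float(np.sum(p * a_mats[k]))
            score[k] = -0.5 * (tr_pa - float(py @ q[:, k]))
        q[:, K] = py
        score[K] = -0.5 * (float(np.trace(p)) - float(py @ py))

        def em_delta():
            d = np.empty(K + 1)
            for k in range(K):
                tr_pa = float(np.sum(p * a_mats[k]))
                d[k] = (sigma[k] ** 2 / n) * (float(py @ q[:, k]) - tr_pa)
            d[K] = (sigma[K] ** 2 / n) * (float(py @ py) - float(np.trace(p)))
            return d

        if it == 1:
            # one EM step for stability
            delta = em_delta()
        else:
            ai = 0.5 * (q.T @ p @ q)
            if np.linalg.cond(ai) > 1e12:
                raise NonIdentifiableError(
                    "AI matrix singular: variance components are confounded "
                    "(is a GRM proportional to the identity?)"
                )
            delta = np.linalg.solve(ai, score)

        def try_step(direction):
            step = 1.0
            for _ in range(30):
                cand = np.clip(sigma + step * direction, floor, None)
                try:
                    p_new, py_new, ll_new = _reml_pieces(build_v(cand), X, y)
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if ll_new >= ll - 1e-10:
                    return cand, p_new, py_new, ll_new
                step *= 0.5
            return None

        hit = try_step(delta)
        if hit is None and it > 1:
            # the AI direction can point downhill for the free components
            # once another component is clamped at the floor; EM is always
            # an ascent direction
            hit = try_step(em_delta())
        if hit is not None:
            sigma, p, py, ll_new = hit
            accepted = True
        else:
            accepted = False
        if not accepted:
            converged = True
            message = "no uphill step found; treating current point as optimum"
            break
        ll_path.append(ll_new)
        if abs(ll_new - ll) < tol and it > 1:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    else:
        message = f"not converged in {max_iter} iterations"
        warnings.warn(message)

    # final AI and sampling covariance
    q = np.empty((n, K + 1))
    for k in range(K):
        q[:, k] = a_mats[k] @ py
    q[:, K] = py
    ai = 0.5 * (q.T @ p @ q)
    if np.linalg.cond(ai) > 1e12:
        cov = np.linalg.pinv(ai)
    else:
        cov = np.linalg.inv(ai)

    total = sigma.sum()
    h2 = sigma / total
    grad = -np.outer(sigma, np.ones(K + 1)) / total ** 2 + np.eye(K + 1) / total
    h2_var = np.einsum("ki,ij,kj->k", grad, cov, grad)
    h2_se = np.sqrt(np.clip(h2_var, 0.0, None))

    return GremlFit(
        sigma2=sigma,
        cov_sigma2=cov,
        loglik=ll,
        h2=h2,
        h2_se=h2_se,
        converged=converged,
        n_iter=n_iter,
        floored=sigma <= floor * (1 + 1e-9),
        message=message,
        ll_path=ll_path,
    )


def genetic_share(fit: GremlFit) -> tuple:
    """Total genetic h2 (sum of the K genetic shares) with delta-method SE."""
    K = fit.sigma2.size - 1
    total = fit.sigma2.sum()
    share = fit.sigma2[:K].sum() / total
    # d share / d sigma_j: (delta_{j<K} * total - sum_g) / total^2
    sum_g = fit.sigma2[:K].sum()
    grad = np.full(K + 1, -sum_g / total ** 2)
    grad[:K] += 1.0 / total
    var = float(grad @ fit.cov_sigma2 @ grad)
    return float(share), float(np.sqrt(max(var, 0.0)))


def lrt_component(fit_full: GremlFit, fit_reduced: GremlFit):
    """Boundary likelihood-ratio test for one dropped variance component.

    Returns ``(lrt, p)`` with LRT = 2 (ll_full - ll_reduced) clipped at
    zero and p from the boundary mixture 0.5 chi2_0 + 0.5 chi2_1, i.e.
    p = 0.5 * P(chi2_1 > LRT); LRT = 0 gives p = 0.5.
    """
    diff = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if diff < -1e-6:
        warnings.warn(
            f"full model log-likelihood below reduced by {-diff / 2:.3g}; "
            "consider refitting with tighter tolerance"
        )
    lrt = max(0.0, diff)
    p = 0.5 * float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 0.5
    return lrt, p


# ----------------------------------------------------------------------
# conveniences

def covariate_design(covariates: pd.DataFrame | None, n: int | None = None) -> np.ndarray:
    """Intercept + covariate design; ``site`` columns are one-hot encoded."""
    if covariates is None:
        return np.ones((n, 1))
    cols = [np.ones(len(covariates))]
    for name in covariates.columns:
        v = covariates[name].to_numpy(dtype=float)
        if name == "site":
            codes = np.unique(v)
            for c in codes[1:]:  # first level absorbed by the intercept
                cols.append((v == c).astype(float))
        else:
            cols.append(v)
    return np.column_stack(cols)


def partitioned_greml(panel, assignment, y, covariates=None, labels=None, **fit_kwargs):
    """Fit one GRM per partition label plus residual; returns (fit, labels, grms).

    Labels with zero SNPs are dropped (with the returned label list
    reflecting the fitted order).
    """
    from .relatedness import compute_grm

    if labels is None:
        labels = [lab for lab in ("coding", "buffer", "rest")]
    used, grms = [], []
    for lab in labels:
        idx = assignment.indices(lab)
        if idx.size == 0:
            continue
        grms.append(compute_grm(panel, idx))
        used.append(lab)
    X = covariate_design(covariates, n=panel.n_samples)
    fit = fit_greml(VarianceComponentModel(grms=grms, X=X, y=y), **fit_kwargs)
    return fit, used, grms
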