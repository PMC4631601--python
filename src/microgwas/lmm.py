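"""Univariate linear mixed model with a single genetic variance component.

Model: ``y ~ N(X beta, sigma_g^2 K + sigma_e^2 I)``. Writing
``lambda = sigma_g^2 / sigma_e^2`` and rotating by the eigenvectors of K
(``K = U D U^T``) turns the covariance diagonal — ``sigma_e^2 (lambda D + I)``
— so each likelihood evaluation is O(n) after a single eigendecomposition.
beta and sigma_e^2 are profiled out analytically; the profiled (restricted)
log-likelihood is maximized over log10(lambda) in [-5, 5] by a coarse grid
followed by Brent refinement, which guards against the multimodality of the
profiled surface.

Association tests are likelihood-ratio tests with ML fits (REML likelihoods
are not comparable across fixed-effect changes); lambda is re-optimized
under both the null and the alternative. Variance-component ("chip")
heritability uses REML, with the trace normalization of K folded into the
PVE formula and a delta-method standard error from the inverse observed
information of (sigma_g^2, sigma_e^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io import KinshipMatrix

__all__ = [
    "LmmFit",
    "PveEstimate",
    "eigendecompose_kinship",
    "fit_lmm",
    "lrt_predictor",
    "estimate_pve",
    "scan_snps",
    "genomic_control_lambda",
]

_LOG10_LAMBDA_RANGE = (-5.0, 5.0)
_N_GRID = 50


@dataclass
class LmmFit:
    lam: float  # variance ratio sigma_g^2 / sigma_e^2 at the ML optimum
    sigma_g2: float
    sigma_e2: float
    log_likelihood: float  # maximized ML
    restricted_log_likelihood: float  # maximized REML (its own lambda)
    lam_reml: float
    beta: np.ndarray
    beta_se: np.ndarray
    boundary: bool  # lambda optimizer pinned at the search boundary


@dataclass
class PveEstimate:
    """Chip heritability: proportion of variance explained by all SNPs.

    ``nonzero`` follows the interval rule: the estimate is called non-zero
    when the +/- 1 SE band does not include zero, i.e. pve - se > 0.
    """

    pve: float
    se: float

    @property
    def nonzero(self) -> bool:
        return bool(self.pve - self.se > 0)


def eigendecompose_kinship(K: KinshipMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose a kinship matrix; tiny negative eigenvalues are clipped."""
    A = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    if not np.isfinite(A).all():
        raise ValueError("kinship matrix contains non-finite entries")
    d, U = np.linalg.eigh(A)
    if (d < -1e-8 * max(1.0, d.max())).any():
        import warnings

        warnings.warn("clipping negative kinship eigenvalues at zero", stacklevel=2)
    return np.clip(d, 0.0, None), U


def _profile(lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """GLS profile at fixed lambda: returns (rss, beta, XtVX, sum_log_v)."""
    v = lam * d + 1.0
    w = 1.0 / v
    Xw = Xt * w[:, None]
    XtVX = Xt.T @ Xw
    beta = np.linalg.solve(XtVX, Xw.T @ yt)
    resid = yt - Xt @ beta
    rss = float(np.sum(resid**2 * w))
    return rss, beta, XtVX, float(np.sum(np.log(v)))


def _ml_loglik(lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    n = yt.size
    rss, _, _, sumlogv = _profile(lam, d, yt, Xt)
    return -0.5 * (n * (np.log(2 * np.pi) + 1.0) + n * np.log(rss / n) + sumlogv)


def _reml_loglik(lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    n, k = Xt.shape
    rss, _, XtVX, sumlogv = _profile(lam, d, yt, Xt)
    sign, logdet_v = np.linalg.slogdet(XtVX)
    _, logdet_0 = np.linalg.slogdet(Xt.T @ Xt)
    return -0.5 * (
        (n - k) * (np.log(2 * np.pi) + 1.0)
        + (n - k) * np.log(rss / (n - k))
        + sumlogv
        + logdet_v
        - logdet_0
    )


def _maximize_lambda(fun) -> tuple[float, float, bool]:
    """Grid over log10(lambda) then Brent refinement; returns (lam, value, at_boundary)."""
    lo, hi = _LOG10_LAMBDA_RANGE
    grid = np.linspace(lo, hi, _N_GRID)
    vals = np.array([fun(10.0**g) for g in grid])
    j = int(np.argmax(vals))
    if j in (0, _N_GRID - 1):
        a = grid[max(j - 1, 0)]
        b = grid[min(j + 1, _N_GRID - 1)]
    else:
        a, b = grid[j - 1], grid[j + 1]
    res = optimize.minimize_scalar(
        lambda g: -fun(10.0**g), bounds=(a, b), method="bounded",
        options={"xatol": 1e-6},
    )
    cand = [(10.0 ** grid[j], vals[j]), (10.0 ** res.x, -res.fun)]
    lam, val = max(cand, key=lambda t: t[1])
    boundary = np.log10(lam) <= lo + 1e-3 or np.log10(lam) >= hi - 1e-3
    return float(lam), float(val), bool(boundary)


def _as_rotated(y, X, K_or_eig):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if isinstance(K_or_eig, tuple):
        d, U = K_or_eig
    else:
        d, U = eigendecompose_kinship(K_or_eig)
    return d, U, U.T @ y, U.T @ X


def fit_lmm(y, X, K) -> LmmFit:
    """Fit the LMM by ML and REML; K may be a KinshipMatrix or (eigvals, U)."""
    d, U, yt, Xt = _as_rotated(y, X, K)
    n, k = Xt.shape
    if n < k + 2:
        raise ValueError("need n >= #fixed effects + 2")
    if np.linalg.matrix_rank(Xt) < k:
        raise ValueError("singular fixed-effect design")
    lam_ml, ll_ml, bnd_ml = _maximize_lambda(lambda l: _ml_loglik(l, d, yt, Xt))
    lam_reml, ll_reml, bnd_reml = _maximize_lambda(lambda l: _reml_loglik(l, d, yt, Xt))
    rss, beta, XtVX, _ = _profile(lam_ml, d, yt, Xt)
    sigma_e2 = rss / n
    se = np.sqrt(np.diag(np.linalg.inv(XtVX)) * rss / (n - k))
    return LmmFit(
        lam=lam_ml,
        sigma_g2=lam_ml * sigma_e2,
        sigma_e2=sigma_e2,
        log_likelihood=ll_ml,
        restricted_log_likelihood=ll_reml,
        lam_reml=lam_reml,
        beta=beta,
        beta_se=se,
        boundary=bnd_ml or bnd_reml,
    )


def lrt_predictor(y, x, W, K) -> tuple[float, float, float]:
    """Mixed-model LRT for one predictor: returns (beta, se, p).

    Both the null (covariates W only) and alternative (W plus x) models are
    ML-fitted with lambda re-optimized; the statistic is referred to
    chi-square with 1 df, negative values clipped to zero.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    design = np.column_stack([W, x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("predictor collinear with covariates")
    d, U, yt, _ = _as_rotated(y, W, K)
    Wt, xt = U.T @ W, U.T @ x
    _, ll0, _ = _maximize_lambda(lambda l: _ml_loglik(l, d, yt, Wt))
    Dt = np.column_stack([Wt, xt])
    lam1, ll1, _ = _maximize_lambda(lambda l: _ml_loglik(l, d, yt, Dt))
    rss, beta, XtVX, _ = _profile(lam1, d, yt, Dt)
    n, k = Dt.shape
    se = float(np.sqrt(np.linalg.inv(XtVX)[-1, -1] * rss / (n - k)))
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lrt, df=1))
    return float(beta[-1]), se, max(p, np.nextafter(0, 1))


# ---------------------------------------------------------------------------
# chip heritability


def _reml_loglik_varcomp(sg: float, se2: float, d, yt, Xt) -> float:
    """Unprofiled REML log-likelihood in the (sigma_g^2, sigma_e^2) plane."""
    n, k = Xt.shape
    v = sg * d + se2
    if np.any(v <= 0):
        return -np.inf
    w = 1.0 / v
    Xw = Xt * w[:, None]
    XtVX = Xt.T @ Xw
    beta = np.linalg.solve(XtVX, Xw.T @ yt)
    resid = yt - Xt @ beta
    rss = float(np.sum(resid**2 * w))
    _, logdet_v = np.linalg.slogdet(XtVX)
    _, logdet_0 = np.linalg.slogdet(Xt.T @ Xt)
    return -0.5 * (
        (n - k) * np.log(2 * np.pi)
        + float(np.sum(np.log(v)))
        + logdet_v
        - logdet_0
        + rss
    )


def _numeric_hessian(fun, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with one-sided fallback at the boundary."""
    m = theta.size
    h = np.maximum(np.abs(theta) * rel_step, 1e-8)
    H = np.zeros((m, m))
    f0 = fun(theta)

    def shifted(i, s):
        t = theta.copy()
        t[i] += s
        return t

    for i in range(m):
        lo_ok = theta[i] - h[i] > 0
        if lo_ok:
            H[i, i] = (fun(shifted(i, h[i])) - 2 * f0 + fun(shifted(i, -h[i]))) / h[i] ** 2
        else:
            H[i, i] = (fun(shifted(i, 2 * h[i])) - 2 * fun(shifted(i, h[i])) + f0) / h[i] ** 2
    for i in range(m):
        for j in range(i + 1, m):
            lo_i = theta[i] - h[i] > 0
            lo_j = theta[j] - h[j] > 0
            if lo_i and lo_j:
                fpp = fun(_bump(theta, {i: h[i], j: h[j]}))
                fpm = fun(_bump(theta, {i: h[i], j: -h[j]}))
                fmp = fun(_bump(theta, {i: -h[i], j: h[j]}))
                fmm = fun(_bump(theta, {i: -h[i], j: -h[j]}))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
            else:
                fpp = fun(_bump(theta, {i: h[i], j: h[j]}))
                fp0 = fun(_bump(theta, {i: h[i]}))
                f0p = fun(_bump(theta, {j: h[j]}))
                H[i, j] = H[j, i] = (fpp - fp0 - f0p + f0) / (h[i] * h[j])
    return H


def _bump(theta: np.ndarray, deltas: dict[int, float]) -> np.ndarray:
    t = theta.copy()
    for i, dv in deltas.items():
        t[i] += dv
    return t


def estimate_pve(y, K, X=None) -> PveEstimate:
    """REML chip heritability of y given the relatedness matrix K.

    ``PVE = c sigma_g^2 / (c sigma_g^2 + sigma_e^2)`` with ``c = tr(K)/n``,
    so K keeps its natural scale. The SE comes from the delta method applied
    to the numerically inverted observed information of the variance
    components; when the information is degenerate (typically a boundary
    estimate) the SE is reported as the estimate's distance-to-zero plus
    one, which never asserts non-zero heritability.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("zero-variance trait")
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    A = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    c = float(np.trace(A) / n)
    d, U, yt, Xt = _as_rotated(y, X, (*eigendecompose_kinship(A),))
    k = Xt.shape[1]
    lam, _, _ = _maximize_lambda(lambda l: _reml_loglik(l, d, yt, Xt))
    rss, _, _, _ = _profile(lam, d, yt, Xt)
    se2 = rss / (n - k)
    sg = lam * se2
    pve = c * sg / (c * sg + se2)

    theta = np.array([sg, se2])
    H = _numeric_hessian(lambda t: _reml_loglik_varcomp(t[0], t[1], d, yt, Xt), theta)
    grad = np.array(
        [c * se2 / (c * sg + se2) ** 2, -c * sg / (c * sg + se2) ** 2]
    )
    se_pve = np.nan
    try:
        cov = np.linalg.inv(-H)
        var = float(grad @ cov @ grad)
        if var > 0 and np.isfinite(var):
            se_pve = float(np.sqrt(var))
    except np.linalg.LinAlgError:
        pass
    if not np.isfinite(se_pve):
        se_pve = pve + 1.0  # degenerate information: refuse to call non-zero
    return PveEstimate(pve=float(pve), se=se_pve)


# ---------------------------------------------------------------------------
# vectorized genome scan


def _scan_stats(w, c, yt, X, X2):
    """Weighted simple-regression pieces for all SNPs at once.

    ``w`` is either (n,) shared weights or (n, p) per-SNP weights; ``c`` is
    the rotated intercept, ``X`` the rotated SNP matrix.
    """
    if w.ndim == 1:
        scc = float(np.dot(c * c, w))
        scy = float(np.dot(c * yt, w))
        syy = float(np.dot(yt * yt, w))
        scx = (c * w) @ X
        sxy = (yt * w) @ X
        sxx = w @ X2
        sumlogv = np.full(X.shape[1], -float(np.sum(np.log(w))))  # sum log v, v = 1/w
    else:
        scc = (c * c) @ w
        scy = (c * yt) @ w
        syy = (yt * yt) @ w
        scx = np.einsum("n,np,np->p", c, X, w)
        sxy = np.einsum("n,np,np->p", yt, X, w)
        sxx = np.einsum("np,np->p", X2, w)
        sumlogv = -np.sum(np.log(w), axis=0)
    sxx_c = sxx - scx**2 / scc
    sxy_c = sxy - scx * scy / scc
    syy_c = syy - scy**2 / scc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx_c > 0, sxy_c / np.where(sxx_c > 0, sxx_c, 1.0), 0.0)
    rss1 = np.maximum(syy_c - beta**2 * sxx_c, 1e-300)
    return beta, sxx_c, rss1, syy_c, sumlogv


def scan_snps(
    y: np.ndarray,
    snps: np.ndarray,
    K_eig: tuple[np.ndarray, np.ndarray],
    mode: str = "exact",
    lam_null: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-SNP mixed-model LRT scan with an intercept-only fixed design.

    ``mode='exact'`` re-optimizes lambda per SNP (grid over log10 lambda plus
    a parabolic refinement of the profiled ML log-likelihood); ``'fast'``
    reuses the null-model lambda for every SNP, reducing each test to a
    weighted simple regression — the shortcut used inside permutation loops.

    Returns arrays ``beta``, ``se``, ``p``, plus the fitted null lambda.
    """
    y = np.asarray(y, dtype=float)
    d, U = K_eig
    n = y.size
    yt = U.T @ y
    c = U.T @ np.ones(n)
    X = U.T @ np.asarray(snps, dtype=float)
    X2 = X * X
    p = X.shape[1]

    Wt = c[:, None]
    if lam_null is None:
        lam_null, ll0_at_lam, _ = _maximize_lambda(lambda l: _ml_loglik(l, d, yt, Wt))
    else:
        ll0_at_lam = _ml_loglik(lam_null, d, yt, Wt)

    def ml_from_rss(rss, sumlogv):
        return -0.5 * (n * (np.log(2 * np.pi) + 1.0) + n * np.log(rss / n) + sumlogv)

    if mode == "fast":
        w = 1.0 / (lam_null * d + 1.0)
        beta, sxx_c, rss1, syy_c, _ = _scan_stats(w, c, yt, X, X2)
        lrt = n * np.log(syy_c / rss1)  # shared sum log v cancels
        lam_per_snp = np.full(p, lam_null)
    elif mode == "exact":
        _, ll0, _ = _maximize_lambda(lambda l: _ml_loglik(l, d, yt, Wt))
        grid = np.linspace(*_LOG10_LAMBDA_RANGE, 41)
        lls = np.empty((grid.size, p))
        for gi, g in enumerate(grid):
            w = 1.0 / (10.0**g * d + 1.0)
            _, _, rss1, _, sumlogv = _scan_stats(w, c, yt, X, X2)
            lls[gi] = ml_from_rss(rss1, sumlogv)
        j = np.argmax(lls, axis=0)
        ll_best = lls[j, np.arange(p)]
        # parabolic refinement in log10(lambda) for interior maxima
        interior = (j > 0) & (j < grid.size - 1)
        g_ref = grid[j].astype(float)
        if interior.any():
            jm, jc = j[interior] - 1, j[interior]
            f_m, f_c, f_p = (
                lls[jm, np.nonzero(interior)[0]],
                lls[jc, np.nonzero(interior)[0]],
                lls[jc + 1, np.nonzero(interior)[0]],
            )
            denom = f_m - 2 * f_c + f_p
            step = np.where(np.abs(denom) > 1e-12, 0.5 * (f_m - f_p) / denom, 0.0)
            g_ref[interior] = grid[jc] + np.clip(step, -1.0, 1.0) * (grid[1] - grid[0])
        lam_per_snp = 10.0**g_ref
        w = 1.0 / (np.outer(d, lam_per_snp) + 1.0)
        beta_r, sxx_r, rss_r, _, sumlogv_r = _scan_stats(w, c, yt, X, X2)
        ll_ref = ml_from_rss(rss_r, sumlogv_r)
        use_ref = ll_ref >= ll_best
        ll1 = np.where(use_ref, ll_ref, ll_best)
        lam_per_snp = np.where(use_ref, lam_per_snp, 10.0 ** grid[j])
        lrt = 2.0 * (ll1 - ll0)
    else:
        raise ValueError(f"unknown scan mode {mode!r}")

    # final beta/se at the per-SNP lambda
    w = 1.0 / (np.outer(d, lam_per_snp) + 1.0) if mode == "exact" else 1.0 / (lam_null * d + 1.0)
    beta, sxx_c, rss1, _, _ = _scan_stats(w, c, yt, X, X2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss1 / (n - 2) / np.where(sxx_c > 0, sxx_c, np.nan))
    lrt = np.clip(lrt, 0.0, None)
    pvals = stats.chi2.sf(lrt, df=1)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    return {"beta": beta, "se": se, "p": pvals, "lam_null": lam_null}


def null_lambda_rotated(yt: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """ML variance-ratio of the intercept-only null model, rotated inputs."""
    lam, _, _ = _maximize_lambda(lambda l: _ml_loglik(l, d, yt, c[:, None]))
    return lam


def genomic_control_lambda(pvals: np.ndarray) -> float:
    """Median chi-square inflation factor of a p-value vector."""
    chi = stats.chi2.isf(np.asarray(pvals, dtype=float), df=1)
    return float(np.median(chi) / stats.chi2.isf(0.5, df=1))
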