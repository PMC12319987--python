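"""Factor-analytic machinery for the dependent-lateralization hypothesis.

Covers the assumption checks (Bartlett sphericity, KMO sampling adequacy,
variance inflation factors, the Doornik–Hansen omnibus multivariate
normality test), exploratory factoring (iterated principal-axis extraction
with parallel analysis for retention), and a maximum-likelihood
confirmatory factor model with χ², CFI, RMSEA, and SRMR fit indices.

The CFA fixes factor variances at 1 and, by default, the factor covariance
at 0; for p indicators with simple structure this leaves
p(p+1)/2 − 2p degrees of freedom (df = 2 at p = 4). A free factor
covariance (df = 1 at p = 4) is available via ``factor_covariance="free"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FactorModel",
    "bartlett_sphericity",
    "kmo",
    "vif",
    "doornik_hansen",
    "efa_principal_factors",
    "parallel_analysis",
    "cfa_fit",
]


# ---------------------------------------------------------------------------
# assumption tests
# ---------------------------------------------------------------------------

def _check_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must have a unit diagonal")
    return R


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that a correlation matrix is an identity matrix.

    χ² = −(n − 1 − (2p + 5)/6)·ln|R| on p(p−1)/2 df.
    """
    R = _check_corr(R)
    p = R.shape[0]
    if n <= p:
        raise ValueError("need n > p")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular or indefinite correlation matrix")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    chi2 = max(chi2, 0.0)
    df = p * (p - 1) // 2
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


def kmo(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser–Meyer–Olkin sampling adequacy, overall and per variable.

    KMO = Σr²/(Σr² + Σq²) over off-diagonal entries, where q are the
    anti-image partial correlations from R⁻¹. For any 2-variable matrix the
    partial equals the marginal correlation, forcing KMO = 0.5.
    """
    R = _check_corr(R)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular correlation matrix") from exc
    d = 1.0 / np.sqrt(np.diag(Rinv))
    Q = -Rinv * np.outer(d, d)  # partial correlations (off-diagonal)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R**2) * off
    q2 = (Q**2) * off
    overall = r2.sum() / (r2.sum() + q2.sum())
    per_var = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    return float(overall), per_var


def vif(data) -> pd.Series:
    """Variance inflation factor 1/(1−R²_j) per variable.

    R²_j comes from an OLS of variable j on all others (with intercept).
    Perfect collinearity is reported as ``inf``.
    """
    X = pd.DataFrame(data)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than variables")
    if (X.std(ddof=1) == 0).any():
        raise ValueError("constant column")
    out = {}
    A = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        others = np.delete(A, j, axis=1)
        D = np.column_stack([np.ones(n), others])
        y = A[:, j]
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def doornik_hansen(data) -> tuple[float, int, float]:
    """Doornik–Hansen omnibus test of multivariate normality.

    Columns are standardized and orthogonalized through the eigenstructure
    of their correlation matrix; each component's skewness and kurtosis are
    mapped to approximate standard normals (the D'Agostino skewness
    transform and a gamma-approximation kurtosis transform conditional on
    skewness); the statistic is the sum of squares, χ²(2p) under normality.
    """
    X = np.asarray(pd.DataFrame(data), dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise np.linalg.LinAlgError("constant column: singular covariance")
    Xs = Xc / sd
    R = np.corrcoef(Xs, rowvar=False)
    if p == 1:
        R = np.array([[1.0]])
    lam, V = np.linalg.eigh(R)
    if lam.min() <= 1e-12:
        raise np.linalg.LinAlgError("singular correlation matrix")
    Z = Xs @ V @ np.diag(lam**-0.5) @ V.T

    m2 = (Z**2).mean(axis=0)
    m3 = (Z**3).mean(axis=0)
    m4 = (Z**4).mean(axis=0)
    rtb1 = m3 / m2**1.5
    b2 = m4 / m2**2

    # skewness -> z1 (D'Agostino)
    beta = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1.0 + np.sqrt(2.0 * (beta - 1.0))
    delta = 1.0 / np.sqrt(np.log(np.sqrt(w2)))
    y = rtb1 * np.sqrt((w2 - 1.0) * (n + 1) * (n + 3) / (12.0 * (n - 2)))
    z1 = delta * np.log(y + np.sqrt(y**2 + 1.0))

    # kurtosis -> z2 (gamma approximation conditional on skewness)
    dn = (n - 3) * (n + 1) * (n**2 + 15 * n - 4)
    a = (n - 2) * (n + 5) * (n + 7) * (n**2 + 27 * n - 70) / (6.0 * dn)
    c = (n - 7) * (n + 5) * (n + 7) * (n**2 + 2 * n - 5) / (6.0 * dn)
    k = (n + 5) * (n + 7) * (n**3 + 37 * n**2 + 11 * n - 313) / (12.0 * dn)
    alpha = a + rtb1**2 * c
    chi = (b2 - 1.0 - rtb1**2) * 2.0 * k
    chi = np.maximum(chi, 1e-12)
    z2 = (
        np.sqrt(9.0 * alpha)
        * ((chi / (2.0 * alpha)) ** (1.0 / 3.0) - 1.0 + 1.0 / (9.0 * alpha))
    )

    dh = float((z1**2 + z2**2).sum())
    df = 2 * p
    return dh, df, float(stats.chi2.sf(dh, df))


# ---------------------------------------------------------------------------
# exploratory factoring
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    """Loadings and fit summary for an EFA or CFA stage."""

    loadings: pd.DataFrame  # variables × factors
    eigenvalues: np.ndarray
    communalities: pd.Series
    proportion_variance: np.ndarray
    method: str = "efa"
    # CFA extras
    discrepancy: float | None = None
    chi2: float | None = None
    df: int | None = None
    p: float | None = None
    cfi: float | None = None
    rmsea: float | None = None
    srmr: float | None = None
    factor_covariance: float | None = None
    residual_variances: pd.Series | None = None
    n_obs: int | None = None
    converged: bool = True
    spec: dict = field(default_factory=dict, repr=False)


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations: 1 − 1/diag(R⁻¹)."""
    return 1.0 - 1.0 / np.diag(np.linalg.inv(R))


def efa_principal_factors(
    R: np.ndarray,
    n_factors: int,
    names: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FactorModel:
    """Iterated principal-axis factoring of a correlation matrix.

    Initial communalities are the squared multiple correlations; the reduced
    matrix (communalities on the diagonal) is eigendecomposed, loadings are
    the top eigenvectors scaled by root eigenvalues, and communalities are
    updated from the loadings until the largest change falls below ``tol``.
    Heywood communalities are clipped to 1 with a warning. The reported
    proportion of variance is eigenvalue / sum of retained eigenvalues.
    """
    R = _check_corr(R)
    p = R.shape[0]
    if not (1 <= n_factors < p):
        raise ValueError("need 1 <= n_factors < p")
    names = names if names is not None else [f"v{i+1}" for i in range(p)]
    h2 = np.clip(_smc(R), 0.0, 1.0)
    converged = False
    for _ in range(max_iter):
        Rred = R.copy()
        np.fill_diagonal(Rred, h2)
        lam, V = np.linalg.eigh(Rred)
        order = np.argsort(lam)[::-1]
        lam, V = lam[order], V[:, order]
        lam_k = np.clip(lam[:n_factors], 0.0, None)
        L = V[:, :n_factors] * np.sqrt(lam_k)
        h2_new = (L**2).sum(axis=1)
        if np.any(h2_new > 1.0):
            warnings.warn("Heywood case: communality clipped to 1", stacklevel=2)
            h2_new = np.minimum(h2_new, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            converged = True
            break
        h2 = h2_new
    Rred = R.copy()
    np.fill_diagonal(Rred, h2)
    lam = np.sort(np.linalg.eigvalsh(Rred))[::-1]
    eig = lam[:n_factors]
    # deterministic sign: largest-magnitude loading positive per factor
    for j in range(n_factors):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    total = eig.sum()
    prop = eig / total if total > 0 else np.full(n_factors, np.nan)
    return FactorModel(
        loadings=pd.DataFrame(
            L, index=names, columns=[f"factor{j+1}" for j in range(n_factors)]
        ),
        eigenvalues=eig,
        communalities=pd.Series(h2, index=names),
        proportion_variance=prop,
        method="efa",
        converged=converged,
    )


def reduced_eigenvalues(R: np.ndarray) -> np.ndarray:
    """Eigenvalues of the SMC-reduced correlation matrix, descending."""
    R = _check_corr(R)
    Rred = R.copy()
    np.fill_diagonal(Rred, np.clip(_smc(R), 0.0, 1.0))
    return np.sort(np.linalg.eigvalsh(Rred))[::-1]


def parallel_analysis(
    n: int,
    p: int,
    reps: int,
    seed: int,
    observed_eigenvalues: np.ndarray,
    quantile: float = 0.95,
) -> int:
    """Number of factors whose observed reduced-matrix eigenvalues beat the
    95th percentile of matched random-normal data.

    Random datasets are n × p standard normal; their reduced-correlation
    eigenvalues are collected over ``reps`` draws and compared position by
    position; retention stops at the first observed eigenvalue that fails.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    obs = np.asarray(observed_eigenvalues, dtype=float)
    rng = np.random.default_rng(seed)
    sims = np.empty((reps, p))
    for r in range(reps):
        X = rng.standard_normal((n, p))
        R = np.corrcoef(X, rowvar=False)
        sims[r] = reduced_eigenvalues(R)
    thresh = np.quantile(sims, quantile, axis=0)
    retained = 0
    for i in range(min(obs.size, p)):
        if obs[i] > thresh[i]:
            retained += 1
        else:
            break
    return retained


# ---------------------------------------------------------------------------
# confirmatory factor analysis
# ---------------------------------------------------------------------------

def _cfa_sigma(lam, psi, phi, factor_of, n_fac):
    Lam = np.zeros((lam.size, n_fac))
    Lam[np.arange(lam.size), factor_of] = lam
    Phi = np.eye(n_fac)
    if n_fac == 2:
        Phi[0, 1] = Phi[1, 0] = phi
    return Lam @ Phi @ Lam.T + np.diag(psi)


def _fml(S, Sigma):
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    p = S.shape[0]
    return logdet_sigma - logdet_s + np.trace(S @ np.linalg.inv(Sigma)) - p


def cfa_fit(
    data,
    spec: dict[str, str],
    factor_covariance: str = "fixed_zero",
) -> FactorModel:
    """Maximum-likelihood confirmatory factor analysis with simple structure.

    ``spec`` maps each indicator (column of ``data``) to exactly one factor
    name. Factor variances are fixed at 1; free parameters are one loading
    and one residual variance per indicator, plus the factor covariance if
    ``factor_covariance="free"``. Minimizes
    F_ML = ln|Σ(θ)| − ln|S| + tr(S Σ(θ)⁻¹) − p; T = (n − 1) F_ML on
    df = p(p+1)/2 − (free parameters); CFI against the independence
    (diagonal) baseline, RMSEA = sqrt(max(T−df,0)/(df(n−1))), SRMR over all
    unique standardized residual moments. Loadings are reported
    standardized (λ/√Σ_jj).
    """
    X = pd.DataFrame(data)
    indicators = [c for c in X.columns if c in spec]
    missing = set(spec) - set(X.columns)
    if missing:
        raise KeyError(f"indicators {sorted(missing)} not in data")
    X = X[indicators]
    n, p = X.shape
    factors = sorted(set(spec.values()))
    n_fac = len(factors)
    factor_of = np.array([factors.index(spec[c]) for c in indicators])
    free_phi = factor_covariance == "free"
    if factor_covariance not in ("fixed_zero", "free"):
        raise ValueError(f"unknown factor_covariance {factor_covariance!r}")
    if free_phi and n_fac != 2:
        raise ValueError("free factor covariance is supported for 2 factors")
    n_free = 2 * p + (1 if free_phi else 0)
    df = p * (p + 1) // 2 - n_free
    if df < 0:
        raise ValueError(f"negative degrees of freedom ({df})")
    if n <= n_free:
        raise ValueError("need more observations than free parameters")
    S = np.cov(X.to_numpy(dtype=float), rowvar=False, ddof=1)
    if np.linalg.eigvalsh(S).min() <= 0:
        raise np.linalg.LinAlgError("sample covariance not positive definite")
    s_diag = np.diag(S)

    def unpack(theta):
        lam = theta[:p]
        psi = theta[p : 2 * p]
        phi = theta[2 * p] if free_phi else 0.0
        return lam, psi, phi

    def objective(theta):
        lam, psi, phi = unpack(theta)
        return _fml(S, _cfa_sigma(lam, psi, phi, factor_of, n_fac))

    bounds = (
        [(None, None)] * p
        + [(1e-6, None)] * p
        + ([(-0.999, 0.999)] if free_phi else [])
    )
    x0 = np.concatenate(
        [np.sqrt(s_diag) * 0.7, s_diag * 0.5, [0.0] if free_phi else []]
    )
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(5):
        start = x0 if attempt == 0 else x0 * rng.uniform(0.5, 1.5, x0.size)
        res = optimize.minimize(
            objective, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError("CFA did not converge")
    lam, psi, phi = unpack(best.x)
    fml = float(best.fun)
    T = (n - 1) * fml
    p_val = float(stats.chi2.sf(T, df)) if df > 0 else float("nan")

    # independence baseline
    f_base = _fml(S, np.diag(s_diag))
    T_base = (n - 1) * f_base
    df_base = p * (p - 1) // 2
    denom = max(T_base - df_base, T - df, 0.0)
    cfi = 1.0 - max(T - df, 0.0) / denom if denom > 0 else 1.0
    rmsea = float(np.sqrt(max(T - df, 0.0) / (df * (n - 1)))) if df > 0 else 0.0
    Sigma = _cfa_sigma(lam, psi, phi, factor_of, n_fac)
    scale = np.sqrt(np.outer(s_diag, s_diag))
    resid_std = (S - Sigma) / scale
    iu = np.triu_indices(p)
    srmr = float(np.sqrt((resid_std[iu] ** 2).mean()))

    model_sd = np.sqrt(np.diag(Sigma))
    L_std = np.zeros((p, n_fac))
    L_std[np.arange(p), factor_of] = lam / model_sd
    return FactorModel(
        loadings=pd.DataFrame(L_std, index=indicators, columns=factors),
        eigenvalues=np.array([]),
        communalities=pd.Series((lam / model_sd) ** 2, index=indicators),
        proportion_variance=np.array([]),
        method="cfa",
        discrepancy=fml,
        chi2=float(T),
        df=df,
        p=p_val,
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        rmsea=rmsea,
        srmr=srmr,
        factor_covariance=float(phi) if free_phi else 0.0,
        residual_variances=pd.Series(psi, index=indicators),
        n_obs=n,
        converged=bool(best.success),
        spec=dict(spec),
    )
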