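"""Identifying lateralized networks and the relationships between them.

A network counts as lateralized when the intercept of an OLS model of its
NSAR values on mean-centered age, sex, mean-centered mean framewise
displacement, and handedness is significant at a Bonferroni-corrected
alpha (0.05 / number of networks, displayed as 0.003 for 17 networks but
compared unrounded). Across several datasets, a network must pass in every
dataset with a consistent sign. Networks lateralized in the same direction
are ranked pairwise by stacking their values in long format and regressing
on a 0/1 network indicator plus the covariates — faithful to the original
procedure, which ignores the within-subject pairing (a paired t-test
cross-check is available).

The dependent hypothesis — that stronger left lateralization of one
network accompanies stronger right lateralization of another — is tested
by correlating per-subject averages of like-lateralized (model-adjusted)
NSAR values and by full network × network Pearson matrices with Fisher-z
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import design_with_intercept, ols_fit
from .nsar import NSARTable, _centered_design

__all__ = [
    "LateralizationResult",
    "RelationMatrix",
    "bonferroni_alpha",
    "fit_network_lateralization",
    "fit_all_networks",
    "identify_lateralized",
    "compare_networks_pairwise",
    "average_like_lateralized",
    "correlation_matrix",
]


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test alpha alpha/m. Display layers may round to 3 decimals; all
    comparisons use the exact value."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class InterceptTest:
    network: str
    estimate: float
    se: float
    t: float
    p: float


@dataclass
class LateralizationResult:
    """Per-network intercept tests plus attached directions at a given alpha."""

    tests: pd.DataFrame  # index network; estimate, se, t, p
    corrected_alpha: float

    def direction(self, network: str) -> str:
        row = self.tests.loc[network]
        if row["p"] < self.corrected_alpha:
            return "left" if row["estimate"] < 0 else "right"
        return "none"

    def lateralized(self) -> dict[str, str]:
        return {
            net: self.direction(net)
            for net in self.tests.index
            if self.direction(net) != "none"
        }


def _covariate_design(table: NSARTable) -> np.ndarray:
    cov = table.require_covariates()
    return design_with_intercept(_centered_design(cov))


def fit_all_networks(table: NSARTable, alpha: float = 0.05) -> LateralizationResult:
    """Intercept test for every network at the Bonferroni-corrected level.

    One OLS per network of NSAR on the four centered covariates; with the
    covariates centered, the intercept estimates the population mean NSAR,
    and its two-sided t test is the lateralization test.
    """
    X = _covariate_design(table)
    n, k = X.shape
    if n < k + 6:
        raise ValueError("need at least 6 more subjects than parameters")
    Y = table.values.to_numpy(dtype=float)
    fit = ols_fit(X, Y)
    tests = pd.DataFrame(
        {
            "estimate": fit.coef[0],
            "se": fit.se[0],
            "t": fit.t[0],
            "p": fit.p[0],
        },
        index=table.networks,
    )
    return LateralizationResult(
        tests=tests, corrected_alpha=bonferroni_alpha(alpha, len(table.networks))
    )


def fit_network_lateralization(table: NSARTable, network: str) -> InterceptTest:
    """Intercept test for a single network (see :func:`fit_all_networks`)."""
    res = fit_all_networks(table)
    row = res.tests.loc[network]
    return InterceptTest(
        network=network,
        estimate=float(row["estimate"]),
        se=float(row["se"]),
        t=float(row["t"]),
        p=float(row["p"]),
    )


def identify_lateralized(tables: list[NSARTable], alpha: float = 0.05) -> dict[str, str]:
    """Networks passing the Bonferroni-corrected intercept test in every
    dataset with a consistent direction; returns network -> 'left'/'right'."""
    if not tables:
        raise ValueError("need at least one dataset")
    common = set(tables[0].networks)
    for t in tables[1:]:
        common &= set(t.networks)
    if not common:
        raise ValueError("datasets share no networks")
    results = [fit_all_networks(t, alpha) for t in tables]
    out: dict[str, str] = {}
    for net in sorted(common):
        dirs = {r.direction(net) for r in results}
        if len(dirs) == 1 and dirs != {"none"}:
            out[net] = dirs.pop()
    return out


def compare_networks_pairwise(
    table: NSARTable,
    netA: str,
    netB: str,
    paired_check: bool = False,
):
    """Which of two like-lateralized networks is more lateralized.

    Long-format stacking: two rows per subject (netA's and netB's values),
    regressed on a 0/1 indicator (1 = netB) and the four covariates
    duplicated per row. The indicator coefficient is netB minus netA on the
    raw NSAR scale: for left-lateralized pairs a negative coefficient means
    netB is the more lateralized, for right pairs a positive one. The long
    format ignores the within-subject dependence; ``paired_check=True``
    additionally returns a paired two-sided t test of the difference.
    """
    if netA == netB:
        raise ValueError("network ids must differ")
    cov = table.require_covariates()
    Xc = _centered_design(cov)
    a = table.values[netA].to_numpy(dtype=float)
    b = table.values[netB].to_numpy(dtype=float)
    y = np.concatenate([a, b])
    indicator = np.concatenate([np.zeros_like(a), np.ones_like(b)])
    X = design_with_intercept(np.column_stack([indicator, np.vstack([Xc, Xc])]))
    fit = ols_fit(X, y)
    coef = float(fit.coef[1, 0])
    p = float(fit.p[1, 0])
    if paired_check:
        t_p = stats.ttest_rel(b, a)
        return coef, p, (float(t_p.statistic), float(t_p.pvalue))
    return coef, p


def average_like_lateralized(
    table: NSARTable,
    left_set: list[str],
    right_set: list[str],
):
    """Per-subject means over left- and right-lateralized network sets and
    their Pearson correlation (r, two-sided p)."""
    left_set, right_set = list(left_set), list(right_set)
    if not left_set or not right_set:
        raise ValueError("both sets must be nonempty")
    if set(left_set) & set(right_set):
        raise ValueError("network sets overlap")
    left_avg = table.values[left_set].mean(axis=1).to_numpy()
    right_avg = table.values[right_set].mean(axis=1).to_numpy()
    r, p = stats.pearsonr(left_avg, right_avg)
    return left_avg, right_avg, float(r), float(p)


@dataclass
class RelationMatrix:
    """Symmetric Pearson matrix with p-values and Fisher-z 95% CIs.

    ``display_alpha`` is a rendering convention only: ``masked()`` hides
    entries with p >= display_alpha, but the matrices themselves are
    complete and inference never uses the mask.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    ci_lower: pd.DataFrame
    ci_upper: pd.DataFrame
    display_alpha: float = 0.05

    def masked(self) -> pd.DataFrame:
        out = self.r.copy()
        out[self.p >= self.display_alpha] = np.nan
        np.fill_diagonal(out.values, 1.0)
        return out


def correlation_matrix(
    table: NSARTable,
    networks: list[str] | None = None,
    display_alpha: float = 0.05,
) -> RelationMatrix:
    """Pairwise Pearson correlations between networks' NSAR values.

    p from the t transform with n - 2 df; 95% CIs from the Fisher z
    transform. A constant column yields undefined (NaN) correlations.
    """
    networks = networks if networks is not None else table.networks
    X = table.values[networks].to_numpy(dtype=float)
    n, p_vars = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    constant = np.ptp(X, axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R[:, constant] = np.nan
    R[constant, :] = np.nan
    np.fill_diagonal(R, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = R * np.sqrt((n - 2) / (1 - R**2))
        P = 2 * stats.t.sf(np.abs(tstat), n - 2)
        z = np.arctanh(np.clip(R, -1 + 1e-15, 1 - 1e-15))
    zse = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.975)
    lo = np.tanh(z - zcrit * zse)
    hi = np.tanh(z + zcrit * zse)
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(lo, 1.0)
    np.fill_diagonal(hi, 1.0)
    idx = pd.Index(networks)
    return RelationMatrix(
        r=pd.DataFrame(R, index=idx, columns=idx),
        p=pd.DataFrame(P, index=idx, columns=idx),
        ci_lower=pd.DataFrame(lo, index=idx, columns=idx),
        ci_upper=pd.DataFrame(hi, index=idx, columns=idx),
        display_alpha=display_alpha,
    )
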