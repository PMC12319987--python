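"""Reliability of lateralization estimates: ICC, stability curves, run splits,
and the exact Wilcoxon signed-rank test.

Two-session reliability uses the two-way single-measures intraclass
correlation. The default is the consistency form, whose F-to-ICC identity
for k = 2 sessions, ICC = (F - 1)/(F + 1) with F on (n-1, n-1) degrees of
freedom, matches the degrees-of-freedom pattern reported for two-session
designs. The absolute-agreement form is available behind ``form``.

"Minutes of data" in stability analyses is treated abstractly: callers
supply per-increment value vectors (however obtained) and an independent
reference; the suite never touches raw time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ICCResult",
    "icc_two_session",
    "incremental_stability",
    "split_runs",
    "wilcoxon_signed_rank_exact",
]


@dataclass
class ICCResult:
    icc: float
    F: float
    df1: int
    df2: int
    p: float
    ci_lower: float
    ci_upper: float
    form: str  # "consistency" or "absolute"


def icc_two_session(
    x: np.ndarray,
    y: np.ndarray,
    form: str = "consistency",
    alpha: float = 0.05,
) -> ICCResult:
    """Two-way single-measures ICC for a two-session design.

    ``x`` and ``y`` are per-subject values from sessions 1 and 2. The
    consistency form is ICC(3,1) = (MS_R - MS_E)/(MS_R + MS_E) for k = 2,
    with F = MS_R/MS_E on (n-1, n-1) df and an exact F-based CI. The
    absolute form is ICC(2,1), which additionally penalizes session mean
    shifts; its CI uses the standard Satterthwaite approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    df_rows, df_cols, df_err = n - 1, k - 1, (n - 1) * (k - 1)
    msr = ss_rows / df_rows
    msc = ss_cols / df_cols
    mse = ss_err / df_err
    if ss_total <= 0:
        raise ValueError("zero total variance; ICC undefined")
    if mse <= 0:
        # perfect within-subject agreement
        F = np.inf
        p = 0.0
    else:
        F = msr / mse
        p = float(stats.f.sf(F, df_rows, df_err))

    if form == "consistency":
        if np.isfinite(F):
            icc = (F - 1.0) / (F + k - 1.0)
            fl = F / stats.f.ppf(1 - alpha / 2, df_rows, df_err)
            fu = F * stats.f.ppf(1 - alpha / 2, df_err, df_rows)
            lo = (fl - 1.0) / (fl + k - 1.0)
            hi = (fu - 1.0) / (fu + k - 1.0)
        else:
            icc = lo = hi = 1.0
    elif form == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = (msr - mse) / denom
        # Satterthwaite CI (McGraw & Wong, ICC(A,1))
        if mse > 0 and icc < 1:
            a = (k * icc) / (n * (1 - icc))
            b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
            fc = msc / mse
            v = ((a * fc + b) ** 2) / ((a * fc) ** 2 / df_cols + b**2 / df_err)
            f2u = stats.f.ppf(1 - alpha / 2, df_rows, v)
            f2l = stats.f.ppf(1 - alpha / 2, v, df_rows)
            lo = n * (msr - f2u * mse) / (
                f2u * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f2l * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2l * msr
            )
        else:
            lo = hi = 1.0
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    return ICCResult(
        icc=float(icc),
        F=float(F),
        df1=df_rows,
        df2=df_err,
        p=p,
        ci_lower=float(min(lo, icc)),
        ci_upper=float(max(hi, icc)),
        form=form,
    )


def incremental_stability(
    values_by_increment: dict,
    reference: np.ndarray | pd.Series,
    form: str = "consistency",
) -> pd.DataFrame:
    """ICC of each data increment against an independent reference.

    ``values_by_increment`` maps an increment label (e.g., minutes of data)
    to a per-subject vector aligned with ``reference``. Returns one row per
    increment with the ICC, F, df, and CI.
    """
    ref = np.asarray(reference, dtype=float)
    rows = []
    for inc in sorted(values_by_increment):
        vals = np.asarray(values_by_increment[inc], dtype=float)
        if vals.shape != ref.shape:
            raise ValueError(f"increment {inc!r} is not aligned with the reference")
        r = icc_two_session(vals, ref, form=form)
        rows.append(
            dict(
                increment=inc,
                icc=r.icc,
                F=r.F,
                df1=r.df1,
                df2=r.df2,
                p=r.p,
                ci_lower=r.ci_lower,
                ci_upper=r.ci_upper,
            )
        )
    return pd.DataFrame(rows).set_index("increment")


def split_runs(run_ids: list, scheme: str, seed: int | None = None) -> tuple[list, list]:
    """Split an ordered run list into two disjoint, exhaustive halves.

    even_odd: runs at odd positions (1st, 3rd, ...) vs even positions;
    first_second: first half vs second half; random: a seeded random
    half-split (reproducible for a fixed seed).
    """
    run_ids = list(run_ids)
    if len(run_ids) < 2:
        raise ValueError("need at least 2 runs")
    if scheme == "even_odd":
        return run_ids[0::2], run_ids[1::2]
    if scheme == "first_second":
        half = len(run_ids) // 2
        return run_ids[:half], run_ids[half:]
    if scheme == "random":
        if seed is None:
            raise ValueError("random scheme requires a seed")
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(run_ids))
        half = len(run_ids) // 2
        first = sorted(idx[:half])
        second = sorted(idx[half:])
        return [run_ids[i] for i in first], [run_ids[i] for i in second]
    raise ValueError(f"unknown scheme {scheme!r}")


def wilcoxon_signed_rank_exact(differences: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank V and two-sided p, exact for n ≤ 25.

    Zeros are dropped before ranking; tied absolute differences share
    average ranks. V is the sum of ranks of the positive differences. The
    exact p enumerates all 2^n sign assignments (via a rank-sum counting
    recursion, which is exhaustive enumeration collapsed over equal sums);
    above n = 25 a normal approximation with tie and continuity corrections
    is used. Two-sided p = min(1, 2·min(P(W ≤ V), P(W ≥ V))).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    V = float(ranks[d > 0].sum())
    if n <= 25:
        # doubled ranks are integers even with .5 ties
        r2 = np.round(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        counts /= 2.0**n
        v2 = int(round(2 * V))
        p_le = float(counts[: v2 + 1].sum())
        p_ge = float(counts[v2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(np.round(2 * ranks).astype(int), return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        sd = np.sqrt(var)
        z = (V - mean - 0.5 * np.sign(V - mean)) / sd
        p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return V, p
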