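"""The network surface-area ratio (NSAR) and companions.

For each functional network k the lateralization statistic is

    NSAR_k = (RH_SA_k - LH_SA_k) / (LH_SA_k + RH_SA_k),

the difference of right- and left-hemisphere surface areas over their sum.
It is hard-bounded in [-1, +1]; negative values mean left-hemisphere
lateralization, positive right, zero symmetry. No scaling factor enters the
denominator. A network absent from both hemispheres has no defined NSAR and
is reported as missing, never imputed; a network confined to one hemisphere
sits at the ±1 endpoint.

Covariate adjustment regresses each network's NSAR column on mean-centered
age, mean-centered mean framewise displacement, sex, and handedness (EHI,
-100..100) and subtracts the fitted covariate contributions around their
sample means, so the adjusted values keep the raw sample mean. Adjustment
is idempotent.

The autonomy index is a connectivity-based specialization measure used for
convergent validity: per vertex, the fraction of supra-threshold functional
connections to the ipsilateral hemisphere minus the fraction to the
contralateral hemisphere, normalized by hemisphere vertex counts, then
averaged over a network's vertices in both hemispheres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._ols import design_with_intercept, ols_fit
from .surface import SubjectParcellation, SurfaceMesh, network_surface_area

__all__ = [
    "NSARTable",
    "ConnectivityProfile",
    "compute_nsar",
    "nsar_from_areas",
    "adjust_nsar",
    "autonomy_index",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = ("age", "sex", "mean_fd", "handedness")


@dataclass
class NSARTable:
    """Subjects × networks NSAR values with per-subject covariates.

    ``values``: DataFrame indexed by subject_id, one column per network name.
    ``covariates``: DataFrame indexed by subject_id with columns
    age (years), sex (0/1), mean_fd (mm), handedness (EHI, -100..100).
    """

    values: pd.DataFrame
    covariates: pd.DataFrame | None = None
    adjusted: bool = False
    ground_truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        finite = self.values.to_numpy(dtype=float)
        finite = finite[np.isfinite(finite)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("NSAR values must lie in [-1, 1]")
        if self.covariates is not None:
            if not self.values.index.equals(self.covariates.index):
                self.covariates = self.covariates.loc[self.values.index]

    @property
    def networks(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def require_covariates(self) -> pd.DataFrame:
        if self.covariates is None:
            raise ValueError("this operation needs a covariate table")
        cov = self.covariates[list(COVARIATE_COLUMNS)]
        if cov.isna().any().any():
            raise ValueError("covariates contain missing values")
        return cov


def nsar_from_areas(lh_area: float, rh_area: float) -> float:
    """(RH - LH)/(LH + RH); NaN when the network is absent from both sides."""
    total = lh_area + rh_area
    if total <= 0:
        return float("nan")
    return (rh_area - lh_area) / total


def compute_nsar(
    subject: SubjectParcellation,
    left_mesh: SurfaceMesh,
    right_mesh: SurfaceMesh,
) -> dict[int, float]:
    """Per-network NSAR for one subject from labeled hemisphere meshes."""
    out: dict[int, float] = {}
    for k in subject.network_ids():
        lh = network_surface_area(left_mesh, subject.left, k)
        rh = network_surface_area(right_mesh, subject.right, k)
        val = nsar_from_areas(lh, rh)
        if np.isnan(val):
            warnings.warn(
                f"network {k} absent from both hemispheres of {subject.subject_id}",
                stacklevel=2,
            )
        out[k] = val
    return out


def _centered_design(cov: pd.DataFrame) -> np.ndarray:
    """Covariates entered as deviations from their sample means (all four)."""
    X = cov[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    return X - X.mean(axis=0)


def adjust_nsar(table: NSARTable) -> NSARTable:
    """Regress out covariate effects per network, keeping each network's mean.

    adjusted = raw - Σ_i β_i (x_i - mean x_i), with β from an OLS of the raw
    values on the centered covariates (fit separately per network). A subject
    sitting exactly at the covariate means is untouched; refitting on the
    adjusted table returns coefficients ≈ 0, so the operation is idempotent.
    """
    cov = table.require_covariates()
    Xc = _centered_design(cov)
    n, k = Xc.shape
    if n < k + 2:
        raise ValueError("need at least 2 more subjects than covariates")
    X = design_with_intercept(Xc)
    Y = table.values.to_numpy(dtype=float)
    adj = Y.copy()
    complete = np.isfinite(Y).all(axis=1)
    fit = ols_fit(X[complete], Y[complete])
    # fitted covariate contribution (excluding intercept) around the means
    contrib = Xc @ fit.coef[1:, :]
    adj = Y - contrib
    adj = np.clip(adj, -1.0, 1.0)
    return NSARTable(
        values=pd.DataFrame(adj, index=table.values.index, columns=table.values.columns),
        covariates=table.covariates,
        adjusted=True,
        ground_truth=dict(table.ground_truth),
    )


@dataclass
class ConnectivityProfile:
    """Vertex × vertex correlation matrix spanning both hemispheres.

    ``hemisphere`` holds "left"/"right" per vertex, aligned with the matrix
    rows. The diagonal is ignored by every consumer.
    """

    matrix: np.ndarray
    hemisphere: np.ndarray  # (n,) array of "left"/"right"
    threshold: float = 0.25

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(M, M.T, atol=1e-8):
            raise ValueError("connectivity matrix must be symmetric")
        off = M[~np.eye(M.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        if not (-1.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (-1, 1)")
        self.matrix = M
        self.hemisphere = np.asarray(self.hemisphere)


def autonomy_index(
    profile: ConnectivityProfile,
    parc: SubjectParcellation,
    sign_flip: bool = False,
) -> dict[int, float]:
    """Per-network autonomy index from a thresholded connectivity profile.

    Per vertex v: AI(v) = n_ipsi(v)/N_ipsi - n_contra(v)/N_contra, counting
    connections with correlation above ``profile.threshold`` (diagonal
    excluded); N are the hemisphere vertex counts. The per-network value is
    the mean of AI(v) over the network's vertices in both hemispheres — an
    aggregate that grows with hemispheric specialization regardless of side.
    ``sign_flip`` negates the output.
    """
    labels = np.concatenate([parc.left.labels, parc.right.labels])
    if labels.shape[0] != profile.matrix.shape[0]:
        raise ValueError("profile and parcellation vertex sets disagree")
    is_left = profile.hemisphere == "left"
    n_left, n_right = int(is_left.sum()), int((~is_left).sum())
    supra = profile.matrix > profile.threshold
    np.fill_diagonal(supra, False)
    to_left = supra[:, is_left].sum(axis=1)
    to_right = supra[:, ~is_left].sum(axis=1)
    ai = np.where(
        is_left,
        to_left / n_left - to_right / n_right,
        to_right / n_right - to_left / n_left,
    )
    out: dict[int, float] = {}
    for k in parc.network_ids():
        mask = labels == k
        if not mask.any():
            raise ValueError(f"network {k} has no vertices")
        val = float(ai[mask].mean())
        out[k] = -val if sign_flip else val
    return out


def table_from_subjects(
    nsar_by_subject: dict[str, dict[int, float]],
    label_table: dict[int, str],
    covariates: pd.DataFrame | None = None,
) -> NSARTable:
    """Assemble per-subject compute_nsar outputs into an NSARTable."""
    ids = sorted(k for k in label_table if k != 0)
    rows = {
        sid: [vals.get(k, float("nan")) for k in ids]
        for sid, vals in nsar_by_subject.items()
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[label_table[k] for k in ids]
    )
    df.index.name = "subject_id"
    return NSARTable(values=df, covariates=covariates)
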