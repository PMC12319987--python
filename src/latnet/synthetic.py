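"""Synthetic populations with known lateralization ground truth.

Real individual-specific parcellations come from restricted fMRI datasets;
this module generates stand-ins with every quantity planted and recorded:

* ``generate_population`` draws a subjects × networks NSAR table from a
  linear latent model — per-network mean + two correlated latent factors
  (a "left-lateralization" and a "right-lateralization" factor with a
  negative coupling) + linear covariate effects + Gaussian residual noise —
  truncated to the NSAR range [-1, 1].
* ``render_parcellation`` inverts the surface-area ratio: seeded region
  growing on icosphere hemisphere meshes places contiguous network patches
  whose left/right areas achieve requested NSAR values to within ±0.02.
* ``generate_runs`` perturbs label boundaries to emulate run-to-run
  parcellation variability for reliability analyses.
* ``generate_connectivity`` builds a block-structured vertex×vertex
  correlation matrix (within-network blocks, homotopy-weighted
  cross-hemisphere blocks) for autonomy-index validity checks; the block
  model is a latent-signal construction, so the matrix is positive
  semidefinite before noise by design.

The default scenario mirrors the replicated findings the pipeline is meant
to recover: 3 left-lateralized networks (Language, Dorsal Attention-A,
Default-C), 5 right-lateralized networks (Visual-B, Salience/Ventral
Attention-A, Control-B, Control-C, Limbic-B), and a left/right factor
correlation of -0.65. All outputs are synthetic and bit-reproducible under
a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nsar import NSARTable
from .surface import Parcellation, SubjectParcellation, SurfaceMesh, icosphere_mesh
from .nsar import ConnectivityProfile

__all__ = [
    "YEO17_NETWORKS",
    "SimulationConfig",
    "default_config",
    "generate_population",
    "render_parcellation",
    "render_population",
    "generate_runs",
    "generate_connectivity",
    "implied_network_covariance",
    "implied_average_correlation",
]

YEO17_NETWORKS = (
    "Visual-A",
    "Visual-B",
    "Somatomotor-A",
    "Somatomotor-B",
    "Dorsal Attention-A",
    "Dorsal Attention-B",
    "Salience/Ventral Attention-A",
    "Salience/Ventral Attention-B",
    "Limbic-A",
    "Limbic-B",
    "Control-A",
    "Control-B",
    "Control-C",
    "Default-A",
    "Default-B",
    "Default-C",
    "Language",
)

LEFT_LATERALIZED = ("Language", "Dorsal Attention-A", "Default-C")
RIGHT_LATERALIZED = (
    "Visual-B",
    "Salience/Ventral Attention-A",
    "Control-B",
    "Control-C",
    "Limbic-B",
)

#: planted per-network mean NSAR for the default scenario
DEFAULT_MEANS = {
    "Language": -0.20,
    "Dorsal Attention-A": -0.25,
    "Default-C": -0.15,
    "Visual-B": 0.15,
    "Salience/Ventral Attention-A": 0.10,
    "Control-B": 0.20,
    "Control-C": 0.15,
    "Limbic-B": 0.30,
}


@dataclass
class SimulationConfig:
    """All planted quantities for one synthetic population.

    ``loadings`` is networks × 2 (left factor, right factor);
    ``factor_corr`` couples the two unit-variance factors. Covariate effects
    are scalar slopes shared across networks. ``seed`` is mandatory.
    """

    seed: int
    n_subjects: int = 300
    networks: tuple[str, ...] = YEO17_NETWORKS
    mean_nsar: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    residual_sd: float = 0.10
    factor_loading: float = 0.08
    factor_corr: float = -0.65
    loadings: np.ndarray | None = None  # built from factor_loading if None
    beta_age: float = 0.001  # NSAR units per year
    beta_sex: float = 0.01  # female(0) -> male(1) shift
    beta_fd: float = 0.10  # per mm of mean framewise displacement
    beta_handedness: float = 0.0001  # per EHI unit
    mesh_subdivisions: int = 4
    mesh_radius: float = 100.0
    # fraction of total bilateral area per network; 15% stays unassigned
    # (medial-wall stand-in + feasibility headroom for strongly asymmetric
    # subjects, whose left-hemisphere demand grows as their NSAR sum falls)
    network_area_fraction: float = 0.85 / 17
    boundary_noise: float = 0.05
    seed_mandatory: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.residual_sd <= 0:
            raise ValueError("residual sd must be positive")
        if any(abs(m) > 1 for m in self.mean_nsar.values()):
            raise ValueError("|mean NSAR| must be <= 1")
        if self.loadings is None:
            L = np.zeros((len(self.networks), 2))
            for i, net in enumerate(self.networks):
                if net in LEFT_LATERALIZED:
                    L[i, 0] = self.factor_loading
                elif net in RIGHT_LATERALIZED:
                    L[i, 1] = self.factor_loading
            self.loadings = L
        else:
            self.loadings = np.asarray(self.loadings, dtype=float)
        if not (-1.0 < self.factor_corr < 1.0):
            raise ValueError("factor correlation must produce a PD covariance")

    @property
    def factor_cov(self) -> np.ndarray:
        return np.array([[1.0, self.factor_corr], [self.factor_corr, 1.0]])

    def means_vector(self) -> np.ndarray:
        return np.array([self.mean_nsar.get(net, 0.0) for net in self.networks])

    def label_table(self) -> dict[int, str]:
        return {i + 1: net for i, net in enumerate(self.networks)}


def default_config(seed: int, n_subjects: int = 300, **overrides) -> SimulationConfig:
    return SimulationConfig(seed=seed, n_subjects=n_subjects, **overrides)


def implied_network_covariance(config: SimulationConfig) -> np.ndarray:
    """Population covariance of the NSAR columns implied by the config."""
    L = config.loadings
    return L @ config.factor_cov @ L.T + np.eye(len(config.networks)) * config.residual_sd**2


def implied_average_correlation(
    config: SimulationConfig,
    left_set: tuple[str, ...] = LEFT_LATERALIZED,
    right_set: tuple[str, ...] = RIGHT_LATERALIZED,
) -> float:
    """Population correlation between the left-set and right-set NSAR means.

    This is the generating value that ``average_like_lateralized`` estimates
    on samples from :func:`generate_population`.
    """
    Sigma = implied_network_covariance(config)
    nets = list(config.networks)
    wl = np.zeros(len(nets))
    wr = np.zeros(len(nets))
    for s in left_set:
        wl[nets.index(s)] = 1.0 / len(left_set)
    for s in right_set:
        wr[nets.index(s)] = 1.0 / len(right_set)
    cov = wl @ Sigma @ wr
    return float(cov / np.sqrt((wl @ Sigma @ wl) * (wr @ Sigma @ wr)))


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """HCP-like covariates: age (years), sex (0/1), mean FD (mm), EHI."""
    age = np.clip(rng.normal(28.5, 3.6, n), 22.0, 36.0)
    sex = (rng.random(n) < 0.4).astype(float)  # 1 = male
    fd = np.clip(rng.normal(0.08, 0.02, n), 0.03, 0.20)
    left_hander = rng.random(n) < 0.10
    ehi = np.where(
        left_hander, rng.normal(-50.0, 30.0, n), rng.normal(70.0, 20.0, n)
    )
    ehi = np.clip(ehi, -100.0, 100.0)
    return pd.DataFrame(
        {"age": age, "sex": sex, "mean_fd": fd, "handedness": ehi},
        index=[f"sub-{i+1:04d}" for i in range(n)],
    )


def generate_population(config: SimulationConfig) -> NSARTable:
    """Draw a full NSAR table (with covariates and stored ground truth).

    subject-level NSAR = mean + loadings·factor scores + covariate effects
    + residual noise, truncated to [-1, 1] (warning if > 1% of values are
    clipped). Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, K = config.n_subjects, len(config.networks)
    chol = np.linalg.cholesky(config.factor_cov)
    factors = rng.standard_normal((n, 2)) @ chol.T
    cov = _draw_covariates(rng, n)
    betas = np.array(
        [config.beta_age, config.beta_sex, config.beta_fd, config.beta_handedness]
    )
    Xc = cov.to_numpy() - cov.to_numpy().mean(axis=0)
    covariate_effect = Xc @ betas  # shared across networks
    Y = (
        config.means_vector()[None, :]
        + factors @ config.loadings.T
        + covariate_effect[:, None]
        + rng.standard_normal((n, K)) * config.residual_sd
    )
    clipped = np.mean((Y < -1) | (Y > 1))
    if clipped > 0.01:
        warnings.warn(f"{clipped:.1%} of NSAR values truncated to [-1, 1]", stacklevel=2)
    Y = np.clip(Y, -1.0, 1.0)
    values = pd.DataFrame(Y, index=cov.index, columns=list(config.networks))
    truth = {
        "means": dict(zip(config.networks, config.means_vector())),
        "directions": {
            **{n_: "left" for n_ in LEFT_LATERALIZED if n_ in config.networks},
            **{n_: "right" for n_ in RIGHT_LATERALIZED if n_ in config.networks},
        },
        "factor_corr": config.factor_corr,
        "loadings": config.loadings.copy(),
        "residual_sd": config.residual_sd,
        "implied_average_correlation": implied_average_correlation(config),
        "implied_covariance": implied_network_covariance(config),
        "factor_scores": factors,
    }
    return NSARTable(values=values, covariates=cov, adjusted=False, ground_truth=truth)


# ---------------------------------------------------------------------------
# mesh rendering
# ---------------------------------------------------------------------------

def _grow_regions(
    mesh: SurfaceMesh,
    target_areas: dict[int, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Seeded multi-source region growing to the requested per-label areas.

    Labels are grown round-robin, one frontier vertex at a time; a vertex is
    accepted while it overshoots the target by less than half its own area.
    An exhausted frontier reseeds at a random unassigned vertex, so targets
    are met (to within one vertex) whenever unassigned area remains.
    """
    n = mesh.n_vertices
    va = mesh.vertex_area
    adjacency = mesh.vertex_adjacency()
    labels = np.zeros(n, dtype=np.int64)
    ids = [k for k, a in target_areas.items() if a > 0]
    achieved = {k: 0.0 for k in ids}
    frontiers: dict[int, list[int]] = {k: [] for k in ids}
    seeds = rng.choice(n, size=len(ids), replace=False)
    for k, s in zip(ids, seeds):
        frontiers[k].append(int(s))
    active = set(ids)
    while active:
        for k in list(active):
            target = target_areas[k]
            if achieved[k] >= target:
                active.discard(k)
                continue
            placed = False
            while frontiers[k]:
                v = frontiers[k].pop()
                if labels[v] != 0:
                    continue
                if achieved[k] + va[v] > target + 0.5 * va[v]:
                    continue  # would overshoot by more than half a vertex
                labels[v] = k
                achieved[k] += va[v]
                frontiers[k].extend(int(u) for u in adjacency[v] if labels[u] == 0)
                placed = True
                break
            if not placed:
                unassigned = np.flatnonzero(labels == 0)
                if unassigned.size == 0 or achieved[k] + va[unassigned].min() > target + 0.5 * va[unassigned].min():
                    active.discard(k)
                    continue
                frontiers[k].append(int(rng.choice(unassigned)))
    return labels


def render_parcellation(
    targets: dict[int, float],
    left_mesh: SurfaceMesh,
    right_mesh: SurfaceMesh,
    seed: int,
    label_table: dict[int, str] | None = None,
    area_fractions: dict[int, float] | None = None,
    subject_id: str = "synthetic",
) -> SubjectParcellation:
    """Label maps achieving requested per-network NSAR values.

    ``targets`` maps network id -> NSAR in [-1, 1]; ``area_fractions`` maps
    id -> fraction of the total (bilateral) surface devoted to the network
    (default: equal fractions totalling 94%, the remainder label 0). The
    achieved NSAR (via the area ratio) is within ±0.02 of each target —
    in practice within one vertex area. A target of ±1 places the network
    on one hemisphere only, hitting the endpoint exactly.
    """
    ids = sorted(targets)
    if any(abs(t) > 1 for t in targets.values()):
        raise ValueError("|target NSAR| must be <= 1")
    if area_fractions is None:
        area_fractions = {k: 0.85 / len(ids) for k in ids}
    a_left_total = left_mesh.total_area
    a_right_total = right_mesh.total_area
    total = a_left_total + a_right_total
    left_targets, right_targets = {}, {}
    for k in ids:
        s_k = area_fractions[k] * total
        right_targets[k] = s_k * (1.0 + targets[k]) / 2.0
        left_targets[k] = s_k * (1.0 - targets[k]) / 2.0
    if sum(left_targets.values()) > a_left_total or sum(right_targets.values()) > a_right_total:
        raise ValueError("infeasible targets: requested area exceeds a hemisphere")
    rng = np.random.default_rng(seed)
    lab_l = _grow_regions(left_mesh, left_targets, rng)
    lab_r = _grow_regions(right_mesh, right_targets, rng)
    table = label_table if label_table is not None else {k: f"network_{k}" for k in ids}
    return SubjectParcellation(
        subject_id,
        Parcellation("left", lab_l, table),
        Parcellation("right", lab_r, table),
    )


def render_population(
    table: NSARTable,
    config: SimulationConfig,
    left_mesh: SurfaceMesh | None = None,
    right_mesh: SurfaceMesh | None = None,
) -> tuple[list[SubjectParcellation], SurfaceMesh, SurfaceMesh]:
    """Render one parcellation per subject of an NSAR table on shared meshes."""
    if left_mesh is None:
        left_mesh = icosphere_mesh(config.mesh_subdivisions, config.mesh_radius, "left")
    if right_mesh is None:
        right_mesh = icosphere_mesh(config.mesh_subdivisions, config.mesh_radius, "right")
    name_to_id = {v: k for k, v in config.label_table().items()}
    fractions = {k: config.network_area_fraction for k in name_to_id.values()}
    seed_rng = np.random.default_rng(config.seed + 1)
    subjects = []
    for sid, row in table.values.iterrows():
        targets = {name_to_id[net]: float(val) for net, val in row.items()}
        subjects.append(
            render_parcellation(
                targets,
                left_mesh,
                right_mesh,
                seed=int(seed_rng.integers(2**31)),
                label_table=config.label_table(),
                area_fractions=fractions,
                subject_id=str(sid),
            )
        )
    return subjects, left_mesh, right_mesh


# ---------------------------------------------------------------------------
# run-level perturbation and connectivity
# ---------------------------------------------------------------------------

def generate_runs(
    subject: SubjectParcellation,
    left_mesh: SurfaceMesh,
    right_mesh: SurfaceMesh,
    n_runs: int,
    boundary_noise: float,
    seed: int,
) -> list[SubjectParcellation]:
    """Independently perturbed copies emulating run-level parcellation noise.

    Each run reassigns ``boundary_noise`` of the label-boundary vertices
    (nonzero label with a differently-nonzero-labeled neighbor) to a
    neighboring network's label. Label-0 territory is untouched.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not (0.0 <= boundary_noise < 1.0):
        raise ValueError("boundary_noise must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    adj = {"left": left_mesh.vertex_adjacency(), "right": right_mesh.vertex_adjacency()}
    runs = []
    for r in range(n_runs):
        parts = {}
        for hemi, parc in (("left", subject.left), ("right", subject.right)):
            labels = parc.labels.copy()
            adjacency = adj[hemi]
            boundary = [
                v
                for v in range(labels.size)
                if labels[v] != 0
                and any(labels[u] != 0 and labels[u] != labels[v] for u in adjacency[v])
            ]
            n_flip = int(round(boundary_noise * len(boundary)))
            if n_flip > 0:
                flips = rng.choice(len(boundary), size=n_flip, replace=False)
                for fi in flips:
                    v = boundary[fi]
                    choices = [
                        labels[u]
                        for u in adjacency[v]
                        if labels[u] != 0 and labels[u] != labels[v]
                    ]
                    if choices:  # earlier flips may have absorbed the border
                        labels[v] = choices[rng.integers(len(choices))]
            parts[hemi] = Parcellation(hemi, labels, parc.label_table)
        runs.append(
            SubjectParcellation(f"{subject.subject_id}_run{r+1}", parts["left"], parts["right"])
        )
    return runs


def generate_connectivity(
    subject: SubjectParcellation,
    homotopy: float,
    within_network_r: float = 0.5,
    noise_sd: float = 0.01,
    threshold: float = 0.25,
    seed: int = 0,
) -> ConnectivityProfile:
    """Block-structured symmetric correlation matrix for both hemispheres.

    Derived from a latent-signal model: vertices of network k share a
    bilateral network signal (weight √(homotopy·r)) plus a hemisphere-
    specific signal (weight √((1−homotopy)·r)), giving correlation
    ``within_network_r`` inside a hemisphere patch and ``homotopy ×
    within_network_r`` to the mirrored contralateral patch — positive
    semidefinite by construction. Small symmetric noise is added; if it
    breaks positive semidefiniteness the noise is redrawn (up to 5 tries).
    """
    if not (0.0 <= homotopy <= 1.0):
        raise ValueError("homotopy must lie in [0, 1]")
    n_left = subject.left.n_vertices
    n_total = n_left + subject.right.n_vertices
    if n_total > 2000:
        raise ValueError("connectivity generation is desk-scale: <= 2000 vertices total")
    labels = np.concatenate([subject.left.labels, subject.right.labels])
    hemi = np.array(["left"] * n_left + ["right"] * (subject.right.n_vertices))
    base = np.zeros((n_total, n_total))
    for k in subject.network_ids():
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            continue
        is_l = hemi[members] == "left"
        same = np.equal.outer(is_l, is_l)
        block = np.where(same, within_network_r, homotopy * within_network_r)
        base[np.ix_(members, members)] = block
    np.fill_diagonal(base, 1.0)
    rng = np.random.default_rng(seed)
    for attempt in range(5):
        noise = rng.normal(0.0, noise_sd, (n_total, n_total))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        M = np.clip(base + noise, -1.0, 1.0)
        np.fill_diagonal(M, 1.0)
        if np.linalg.eigvalsh(M).min() > -1e-6:
            return ConnectivityProfile(matrix=M, hemisphere=hemi, threshold=threshold)
    raise RuntimeError("could not draw a positive semidefinite connectivity matrix")
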