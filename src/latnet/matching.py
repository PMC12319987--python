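"""Matching individual parcel clusters to a reference scheme, and overlap metrics.

Individual-specific parcellations come out of a clustering with arbitrary
cluster ids; they are aligned to a canonical network numbering by solving
the assignment problem on the (negative) vertex-overlap matrix with the
Hungarian algorithm, pooling both hemispheres. Agreement between two
matched parcellations is quantified with the dice coefficient, overall or
per network, counting vertices or summing vertex areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .surface import SubjectParcellation, SurfaceMesh

__all__ = ["AssignmentResult", "overlap_matrix", "hungarian_match", "relabel", "dice"]


@dataclass
class AssignmentResult:
    """Optimal bijection individual-cluster-id -> reference-network-id."""

    mapping: dict[int, int]
    total_cost: float
    cost_matrix: np.ndarray
    row_ids: list[int]
    col_ids: list[int]


def _pooled_labels(parc: SubjectParcellation) -> np.ndarray:
    return np.concatenate([parc.left.labels, parc.right.labels])


def _pooled_weights(
    parc: SubjectParcellation,
    weighting: str,
    meshes: tuple[SurfaceMesh, SurfaceMesh] | None,
) -> np.ndarray:
    n = parc.left.n_vertices + parc.right.n_vertices
    if weighting == "vertex_count":
        return np.ones(n)
    if weighting == "area":
        if meshes is None:
            raise ValueError("area weighting requires meshes=(left, right)")
        return np.concatenate([meshes[0].vertex_area, meshes[1].vertex_area])
    raise ValueError(f"unknown weighting {weighting!r}")


def overlap_matrix(
    parcA: SubjectParcellation,
    parcB: SubjectParcellation,
    weighting: str = "vertex_count",
    meshes: tuple[SurfaceMesh, SurfaceMesh] | None = None,
    ids_a: list[int] | None = None,
    ids_b: list[int] | None = None,
) -> tuple[np.ndarray, list[int], list[int]]:
    """Confusion matrix of labels pooled across hemispheres.

    Entry (i, j) is the number (or summed area) of vertices carrying id
    ``ids_a[i]`` in A and ``ids_b[j]`` in B. Label 0 is excluded. Entries
    sum to the total assigned vertex count (or area) restricted to vertices
    nonzero in both parcellations.
    """
    la, lb = _pooled_labels(parcA), _pooled_labels(parcB)
    if la.shape != lb.shape:
        raise ValueError("parcellations have different vertex counts")
    w = _pooled_weights(parcA, weighting, meshes)
    ids_a = ids_a if ids_a is not None else parcA.network_ids()
    ids_b = ids_b if ids_b is not None else parcB.network_ids()
    pos_a = {k: i for i, k in enumerate(ids_a)}
    pos_b = {k: j for j, k in enumerate(ids_b)}
    M = np.zeros((len(ids_a), len(ids_b)))
    mask = (la != 0) & (lb != 0)
    for a, b, wt in zip(la[mask], lb[mask], w[mask]):
        M[pos_a[int(a)], pos_b[int(b)]] += wt
    return M, list(ids_a), list(ids_b)


def hungarian_match(
    cost_matrix: np.ndarray,
    row_ids: list[int] | None = None,
    col_ids: list[int] | None = None,
) -> AssignmentResult:
    """Minimum-cost bijection of rows to columns (Hungarian algorithm).

    For parcel matching, pass cost = negative overlap. The optimal total
    cost is unique; among cost-tied assignments the solver's deterministic
    choice (lowest row index first) is kept.
    """
    C = np.asarray(cost_matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("cost matrix must be square")
    if not np.all(np.isfinite(C)):
        raise ValueError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(C)
    row_ids = row_ids if row_ids is not None else list(range(C.shape[0]))
    col_ids = col_ids if col_ids is not None else list(range(C.shape[1]))
    mapping = {row_ids[r]: col_ids[c] for r, c in zip(rows, cols)}
    return AssignmentResult(
        mapping=mapping,
        total_cost=float(C[rows, cols].sum()),
        cost_matrix=C,
        row_ids=list(row_ids),
        col_ids=list(col_ids),
    )


def match_to_reference(
    individual: SubjectParcellation,
    reference: SubjectParcellation,
    weighting: str = "vertex_count",
    meshes: tuple[SurfaceMesh, SurfaceMesh] | None = None,
) -> AssignmentResult:
    """Hungarian-match an individual's cluster ids onto the reference scheme."""
    M, ids_a, ids_b = overlap_matrix(individual, reference, weighting, meshes)
    return hungarian_match(-M, ids_a, ids_b)


def relabel(parc: SubjectParcellation, assignment: AssignmentResult) -> SubjectParcellation:
    """Apply an assignment's bijection to both hemispheres (label 0 untouched)."""
    mapping = assignment.mapping

    def _relabel_one(p):
        out = np.zeros_like(p.labels)
        for old in np.unique(p.labels):
            if old == 0:
                continue
            if int(old) not in mapping:
                raise KeyError(f"label {int(old)} has no assignment")
            out[p.labels == old] = mapping[int(old)]
        table = {mapping[k]: v for k, v in p.label_table.items() if k in mapping}
        from .surface import Parcellation

        return Parcellation(p.hemisphere, out, table)

    return SubjectParcellation(parc.subject_id, _relabel_one(parc.left), _relabel_one(parc.right))


def dice(
    parcA: SubjectParcellation,
    parcB: SubjectParcellation,
    mode: str = "overall",
    weighting: str = "vertex_count",
    meshes: tuple[SurfaceMesh, SurfaceMesh] | None = None,
):
    """Dice overlap between two matched parcellations, pooled across hemispheres.

    overall: 2·Σ_k|A_k∩B_k| / Σ_k(|A_k|+|B_k|) over nonzero labels.
    per_network: dict id -> 2|A_k∩B_k|/(|A_k|+|B_k|); a network absent from
    both parcellations is reported as NaN (undefined), not 0.
    """
    la, lb = _pooled_labels(parcA), _pooled_labels(parcB)
    if la.shape != lb.shape:
        raise ValueError("parcellations have different vertex counts")
    w = _pooled_weights(parcA, weighting, meshes)
    ids = sorted(set(parcA.network_ids()) | set(parcB.network_ids()))
    inter_total = denom_total = 0.0
    per: dict[int, float] = {}
    for k in ids:
        in_a, in_b = la == k, lb == k
        inter = float(w[in_a & in_b].sum())
        denom = float(w[in_a].sum() + w[in_b].sum())
        inter_total += inter
        denom_total += denom
        per[k] = 2.0 * inter / denom if denom > 0 else float("nan")
    if mode == "overall":
        if denom_total == 0:
            return float("nan")
        return 2.0 * inter_total / denom_total
    if mode == "per_network":
        return per
    raise ValueError(f"unknown mode {mode!r}")
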