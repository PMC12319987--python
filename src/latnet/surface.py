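"""Cortical surface meshes and network label maps.

A hemisphere is represented as a triangulated mesh in mm coordinates
(:class:`SurfaceMesh`), and a functional-network parcellation as a
per-vertex integer label map (:class:`Parcellation`). Label 0 is reserved
for the medial wall / unassigned territory and is excluded from every
network statistic (but participates in conservation checks).

Per-vertex surface area uses the barycentric rule: each vertex receives
one-third of the area of every incident triangle, so vertex areas sum
exactly to the total face area. Network surface area is then the sum of
vertex areas over the vertices carrying that network's label — the
substrate for the surface-area lateralization ratio computed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "SurfaceMesh",
    "Parcellation",
    "SubjectParcellation",
    "compute_vertex_areas",
    "network_surface_area",
    "load_surface",
    "save_surface",
    "load_labels",
    "save_labels",
    "icosphere_mesh",
]


@dataclass
class SurfaceMesh:
    """Triangulated hemisphere surface with derived per-vertex areas (mm²)."""

    hemisphere: str  # "left" or "right"
    vertices: np.ndarray  # (n, 3) float, mm
    faces: np.ndarray  # (m, 3) int, 0-based
    vertex_area: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.vertices.shape[0] == 0:
            raise ValueError("mesh has zero vertices")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise IndexError(
                f"face index out of range: max {self.faces.max()} for {self.n_vertices} vertices"
            )
        if self.vertex_area is None:
            self.vertex_area = compute_vertex_areas(self)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def face_areas(self) -> np.ndarray:
        """Area of every triangle (mm²); degenerate faces contribute 0."""
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @property
    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_adjacency(self) -> list[np.ndarray]:
        """Neighbor vertex indices per vertex (undirected mesh edges); cached."""
        cached = getattr(self, "_adjacency", None)
        if cached is not None:
            return cached
        edges = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.vstack([edges, edges[:, ::-1]])
        edges = np.unique(edges, axis=0)
        neighbors: list[np.ndarray] = []
        split = np.searchsorted(edges[:, 0], np.arange(self.n_vertices + 1))
        for v in range(self.n_vertices):
            neighbors.append(edges[split[v] : split[v + 1], 1])
        self._adjacency = neighbors
        return neighbors


def compute_vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Barycentric per-vertex area: one-third of each incident triangle (mm²).

    Sums exactly (to float precision) to the total face area; degenerate
    zero-area faces contribute nothing; negative areas cannot occur.
    """
    areas = np.zeros(mesh.n_vertices)
    face_areas = mesh.face_areas()
    third = face_areas / 3.0
    for k in range(3):
        np.add.at(areas, mesh.faces[:, k], third)
    return areas


@dataclass
class Parcellation:
    """Per-vertex network labels for one hemisphere (0 = medial wall/unassigned)."""

    hemisphere: str
    labels: np.ndarray  # (n,) int
    label_table: Mapping[int, str]

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.label_table = dict(self.label_table)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_table")

    @property
    def n_vertices(self) -> int:
        return self.labels.shape[0]

    def network_ids(self) -> list[int]:
        """Sorted nonzero ids present in the label table."""
        return sorted(k for k in self.label_table if k != 0)


@dataclass
class SubjectParcellation:
    """Paired left/right parcellations for one subject, sharing a label table."""

    subject_id: str
    left: Parcellation
    right: Parcellation

    def __post_init__(self) -> None:
        if self.left.hemisphere != "left" or self.right.hemisphere != "right":
            raise ValueError("left/right parcellations have wrong hemispheres")
        if dict(self.left.label_table) != dict(self.right.label_table):
            raise ValueError("hemispheres must share one label table")

    @property
    def label_table(self) -> dict[int, str]:
        return dict(self.left.label_table)

    def network_ids(self) -> list[int]:
        return self.left.network_ids()


def network_surface_area(mesh: SurfaceMesh, parc: Parcellation, network_id: int) -> float:
    """Surface area (mm²) of one network on one hemisphere.

    Sums barycentric vertex areas over vertices labeled ``network_id``.
    An id absent from the parcellation returns 0.0 with a warning.
    """
    if parc.n_vertices != mesh.n_vertices:
        raise ValueError(
            f"parcellation has {parc.n_vertices} vertices, mesh has {mesh.n_vertices}"
        )
    if parc.hemisphere != mesh.hemisphere:
        raise ValueError("parcellation/mesh hemisphere mismatch")
    if network_id != 0 and network_id not in parc.label_table:
        warnings.warn(f"network id {network_id} not in label table; area 0", stacklevel=2)
        return 0.0
    return float(mesh.vertex_area[parc.labels == network_id].sum())


# ---------------------------------------------------------------------------
# I/O: GIFTI, FreeSurfer, and a plain-text OFF dump for fixtures
# ---------------------------------------------------------------------------

def load_surface(path, format: str | None = None, hemisphere: str = "left") -> SurfaceMesh:
    """Read a surface mesh from GIFTI (.surf.gii), FreeSurfer binary, or OFF text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _guess_format(path)
    if fmt == "gifti":
        import nibabel as nib

        img = nib.load(str(path))
        coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        return SurfaceMesh(hemisphere, np.asarray(coords, float), np.asarray(faces, np.int64))
    if fmt == "freesurfer":
        from nibabel.freesurfer.io import read_geometry

        coords, faces = read_geometry(str(path))
        return SurfaceMesh(hemisphere, np.asarray(coords, float), np.asarray(faces, np.int64))
    if fmt == "off":
        return _read_off(path, hemisphere)
    raise ValueError(f"unknown surface format {fmt!r}")


def save_surface(mesh: SurfaceMesh, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "gifti":
        import nibabel as nib
        from nibabel.gifti import GiftiDataArray, GiftiImage

        img = GiftiImage(
            darrays=[
                GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    elif fmt == "freesurfer":
        from nibabel.freesurfer.io import write_geometry

        write_geometry(str(path), mesh.vertices, mesh.faces)
    elif fmt == "off":
        _write_off(mesh, path)
    else:
        raise ValueError(f"unknown surface format {fmt!r}")


def load_labels(path, format: str | None = None, hemisphere: str = "left") -> Parcellation:
    """Read a label map from GIFTI (.label.gii) or FreeSurfer .annot."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _guess_format(path)
    if fmt == "gifti":
        import nibabel as nib

        img = nib.load(str(path))
        labels = np.asarray(img.darrays[0].data, dtype=np.int64)
        table: dict[int, str] = {}
        if img.labeltable is not None:
            for lab in img.labeltable.labels:
                if lab.key != 0:
                    table[int(lab.key)] = lab.label
        if not table:
            table = {int(k): f"network_{int(k)}" for k in np.unique(labels) if k != 0}
        return Parcellation(hemisphere, labels, table)
    if fmt == "annot":
        from nibabel.freesurfer.io import read_annot

        labels, _, names = read_annot(str(path))
        labels = np.asarray(labels, dtype=np.int64)
        labels[labels < 0] = 0
        table = {
            i: (n.decode() if isinstance(n, bytes) else str(n))
            for i, n in enumerate(names)
            if i != 0
        }
        return Parcellation(hemisphere, labels, table)
    raise ValueError(f"unknown label format {fmt!r}")


def save_labels(parc: Parcellation, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "gifti":
        import nibabel as nib
        from nibabel.gifti import GiftiDataArray, GiftiImage, GiftiLabel, GiftiLabelTable

        table = GiftiLabelTable()
        rng = np.random.RandomState(0)  # display colors only
        lab0 = GiftiLabel(key=0, red=1, green=1, blue=1, alpha=0)
        lab0.label = "unassigned"
        table.labels.append(lab0)
        for key in sorted(parc.label_table):
            if key == 0:
                continue
            r, g, b = rng.uniform(0.1, 0.9, 3)
            lab = GiftiLabel(key=int(key), red=r, green=g, blue=b, alpha=1)
            lab.label = parc.label_table[key]
            table.labels.append(lab)
        img = GiftiImage(
            darrays=[
                GiftiDataArray(parc.labels.astype(np.int32), intent="NIFTI_INTENT_LABEL")
            ]
        )
        img.labeltable = table
        nib.save(img, str(path))
    else:
        raise ValueError(f"only gifti label output is supported, not {fmt!r}")


def _guess_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gii"):
        return "gifti"
    if name.endswith(".annot"):
        return "annot"
    if name.endswith(".off"):
        return "off"
    return "freesurfer"


def _read_off(path: Path, hemisphere: str) -> SurfaceMesh:
    tokens: list[str] = []
    with open(path) as fh:
        first = fh.readline().strip()
        if first != "OFF":
            raise ValueError(f"{path} is not an OFF file")
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    nv, nf = int(tokens[0]), int(tokens[1])
    idx = 3
    verts = np.array(tokens[idx : idx + 3 * nv], dtype=float).reshape(nv, 3)
    idx += 3 * nv
    faces = []
    for _ in range(nf):
        cnt = int(tokens[idx])
        if cnt != 3:
            raise ValueError("only triangular OFF faces are supported")
        faces.append([int(t) for t in tokens[idx + 1 : idx + 4]])
        idx += 4
    return SurfaceMesh(hemisphere, verts, np.asarray(faces, np.int64))


def _write_off(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def icosphere_mesh(subdivisions: int = 4, radius: float = 100.0, hemisphere: str = "left") -> SurfaceMesh:
    """Icosphere template standing in for a registered hemisphere surface.

    Subdivision 3 gives 642 vertices / 1280 faces; subdivision 4 gives
    2562 / 5120. The geometry is exact, so area-ratio statistics behave as
    on full-resolution cortical meshes.
    """
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(hemisphere, np.asarray(m.vertices, float), np.asarray(m.faces, np.int64))
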