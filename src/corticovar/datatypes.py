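"""Shared in-memory containers for the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectMeta",
    "SurfaceMesh",
    "ThicknessDataset",
    "RegionThicknessTable",
    "BoldRun",
    "ClusterRecord",
]

GROUPS = ("patient", "control")


@dataclass(frozen=True)
class SubjectMeta:
    """One participant: group membership plus the model covariates."""

    id: str
    group: str                      # "patient" | "control"
    age: float                      # years
    sex: str                        # "F" | "M"
    deprivation_days: float | None = None   # patients only
    acuity: float | None = None     # decimal acuity by default (20/32 -> 0.625)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.deprivation_days is not None and self.deprivation_days <= 0:
            raise ValueError("deprivation_days must be positive when present")


def meta_frame(subjects: list[SubjectMeta]) -> pd.DataFrame:
    """Tabular view of subject metadata (one row per subject)."""
    return pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "group": [s.group for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "deprivation_days": [s.deprivation_days for s in subjects],
            "acuity": [s.acuity for s in subjects],
        }
    )


@dataclass
class SurfaceMesh:
    """Triangulated cortical surface in world (MNI-style mm) coordinates.

    ``vertex_area`` is one third of the summed area of each vertex's
    incident triangles, so vertex areas tile the total surface area.
    """

    vertices: np.ndarray            # (N, 3) mm
    triangles: np.ndarray           # (M, 3) int indices
    vertex_area: np.ndarray = field(default=None)  # (N,) mm^2

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.min(initial=0) < 0 or \
                self.triangles.max(initial=-1) >= len(self.vertices):
            raise ValueError("triangle indices out of vertex range")
        if self.vertex_area is None:
            self.vertex_area = self._compute_vertex_area()
        self.vertex_area = np.asarray(self.vertex_area, dtype=float)

    def _compute_vertex_area(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        tri_area = 0.5 * np.linalg.norm(cross, axis=1)
        va = np.zeros(len(v))
        for corner in range(3):
            np.add.at(va, t[:, corner], tri_area / 3.0)
        return va

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges (E, 2), sorted pairs."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def total_area(self) -> float:
        return float(self.vertex_area.sum())


@dataclass
class ThicknessDataset:
    """Per-subject per-vertex cortical thickness on a shared mesh."""

    mesh: SurfaceMesh
    subjects: list[SubjectMeta]
    thickness: np.ndarray           # (n_subjects, n_vertices) mm

    def __post_init__(self):
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.thickness.shape != (len(self.subjects), self.mesh.n_vertices):
            raise ValueError("thickness must be (n_subjects, n_vertices)")
        if not np.all(np.isfinite(self.thickness)) or np.any(self.thickness <= 0):
            raise ValueError("thickness values must be finite and positive")


@dataclass
class RegionThicknessTable:
    """Subjects x regions mean-thickness matrix with region metadata.

    ``regions`` is a DataFrame with columns ``name``, ``hemisphere``,
    ``peak_x``, ``peak_y``, ``peak_z`` (MNI mm).
    """

    subjects: list[SubjectMeta]
    regions: pd.DataFrame
    values: np.ndarray              # (n_subjects, n_regions) mm

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        names = list(self.regions["name"])
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        if self.values.shape != (len(self.subjects), len(names)):
            raise ValueError("values must be (n_subjects, n_regions)")

    @property
    def region_names(self) -> list[str]:
        return list(self.regions["name"])

    def group_values(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.subjects) if s.group == group]
        return self.values[idx]

    def group_subjects(self, group: str) -> list[SubjectMeta]:
        return [s for s in self.subjects if s.group == group]


@dataclass
class BoldRun:
    """One subject's 4-D BOLD run in a common (MNI-like) space."""

    subject: SubjectMeta
    data: np.ndarray                # (X, Y, Z, T)
    tr: float                       # seconds
    affine: np.ndarray              # 4x4 voxel -> world (mm)
    mask: np.ndarray                # (X, Y, Z) bool
    motion: np.ndarray              # (T, 6): 3 translations mm, 3 rotations deg
    wm: np.ndarray                  # (T,)
    csf: np.ndarray                 # (T,)
    global_signal: np.ndarray       # (T,)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        t = self.data.shape[-1]
        if t < 20:
            raise ValueError(f"need at least 20 volumes, got {t}")
        if abs(np.linalg.det(np.asarray(self.affine)[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("brain mask is empty")
        if np.asarray(self.motion).shape != (t, 6):
            raise ValueError("motion table must be (T, 6)")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[-1])

    def world_to_voxel(self, xyz) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        hom = np.c_[xyz, np.ones(len(xyz))]
        return (hom @ inv.T)[:, :3]

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ np.asarray(self.affine).T)[:, :3]


@dataclass
class ClusterRecord:
    """A suprathreshold connected component, surface or volume."""

    peak_index: int                 # vertex index (surface) or flat voxel index
    peak_world: tuple[float, float, float]
    extent: float                   # mm^2 (surface) or voxel count (volume)
    peak_p: float
    sign: int                       # +1 patients > controls, -1 reverse
    members: np.ndarray             # member indices (vertex or flat voxel)
    peak_t: float = 0.0
    corrected_p: float | None = None
    label: str = ""
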