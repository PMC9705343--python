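"""Endocardial electroanatomic voltage-map scar areas.

Bipolar electrogram amplitudes acquired at catheter points are interpolated
onto a triangulated chamber surface.  Nodes farther than the filling-density
threshold (default 5 mm) from every point remain unmapped.  Mapped nodes are
classified by amplitude: dense scar (DS) <= 0.5 mV, heterogeneous tissue
(HT) in (0.5, 1.5] mV, healthy > 1.5 mV, and class areas are tallied in cm2
with fractional assignment of mixed triangles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "EAMStudy",
    "VoltageClassMap",
    "DS_MAX_MV",
    "HT_MAX_MV",
    "classify_amplitude",
    "interpolate_voltage",
    "class_areas",
    "analyze_eam",
]

DS_MAX_MV = 0.5  # dense scar: amplitude <= 0.5 mV
HT_MAX_MV = 1.5  # total scar (DS + HT): amplitude <= 1.5 mV
FILL_THRESHOLD_MM = 5.0  # filling-density threshold for low-voltage regions

_CLASSES = ("DS", "HT", "healthy")


@dataclass
class EAMStudy:
    """Mapping points plus the chamber surface they were acquired on.

    ``points``: (P, 3) mm; ``amplitudes``: (P,) bipolar mV; ``vertices``:
    (N, 3) mm; ``faces``: (M, 3) vertex indices.
    """

    points: np.ndarray
    amplitudes: np.ndarray
    vertices: np.ndarray
    faces: np.ndarray
    fill_threshold: float = FILL_THRESHOLD_MM

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).ravel()
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.points.shape[0] == 0:
            raise ValueError("point set must be nonempty")
        if self.points.shape[0] != self.amplitudes.shape[0]:
            raise ValueError("one amplitude per point required")
        if np.any(self.amplitudes < 0):
            raise ValueError("bipolar amplitudes must be >= 0")
        if self.faces.size == 0 or self.vertices.size == 0:
            raise ValueError("mesh must be nonempty")
        if self.fill_threshold <= 0:
            raise ValueError("fill threshold must be positive")


@dataclass
class VoltageClassMap:
    """Interpolated per-node amplitude and voltage class on the mesh."""

    vertices: np.ndarray
    faces: np.ndarray
    amplitude: np.ndarray  # (N,) mV, NaN where unmapped
    node_class: np.ndarray  # (N,) in {"DS","HT","healthy","unmapped"}

    @property
    def mapped(self) -> np.ndarray:
        return self.node_class != "unmapped"


def classify_amplitude(amp) -> np.ndarray:
    """DS <= 0.5 mV < HT <= 1.5 mV < healthy (boundaries inclusive below)."""
    a = np.asarray(amp, dtype=float)
    out = np.select([a <= DS_MAX_MV, a <= HT_MAX_MV], ["DS", "HT"], default="healthy")
    return str(out[()]) if np.isscalar(amp) or a.ndim == 0 else out


def interpolate_voltage(study: EAMStudy, *, idw_power: float = 2.0) -> VoltageClassMap:
    """Inverse-distance-weighted node amplitudes within the fill radius.

    A node's amplitude is the IDW (power 2) mean of all points within
    ``fill_threshold`` mm; a coincident point wins outright.  Nodes beyond
    the radius from every point are left unmapped (mirroring the clinical
    filling-density rule) and never contribute to areas.
    """
    tree = cKDTree(study.points)
    neighbor_lists = tree.query_ball_point(study.vertices, r=study.fill_threshold)
    n = len(study.vertices)
    amp = np.full(n, np.nan)
    for i, nbrs in enumerate(neighbor_lists):
        if not nbrs:
            continue
        d = np.linalg.norm(study.points[nbrs] - study.vertices[i], axis=1)
        if np.any(d < 1e-9):
            amp[i] = study.amplitudes[nbrs][int(np.argmin(d))]
            continue
        w = d ** (-idw_power)
        amp[i] = float(np.sum(w * study.amplitudes[nbrs]) / np.sum(w))
    node_class = np.full(n, "unmapped", dtype=object)
    mapped = np.isfinite(amp)
    node_class[mapped] = classify_amplitude(amp[mapped])
    return VoltageClassMap(
        vertices=study.vertices,
        faces=study.faces,
        amplitude=amp,
        node_class=np.asarray(node_class, dtype=object),
    )


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    b = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def class_areas(vmap: VoltageClassMap) -> dict[str, float]:
    """Class areas in cm2.

    A triangle whose (mapped) vertices agree by majority (>= 2 of 3) goes
    entirely to that class; otherwise its area is split equally among its
    vertices' classes.  Triangles with any unmapped vertex contribute only
    the mapped fraction of their area.  Returns DS/HT/healthy plus
    ``mapped`` (their sum) and ``total`` mesh area.
    """
    areas = {c: 0.0 for c in _CLASSES}
    fa = _face_areas(vmap.vertices, vmap.faces)  # mm2
    cls = vmap.node_class
    for face, area in zip(vmap.faces, fa):
        labels = [cls[v] for v in face]
        counted = [lab for lab in labels if lab != "unmapped"]
        if not counted:
            continue
        share = area * (len(counted) / 3.0)
        top, cnt = None, 0
        for c in _CLASSES:
            k = counted.count(c)
            if k > cnt:
                top, cnt = c, k
        if cnt >= 2:
            areas[top] += share
        else:  # all three distinct (or fewer mapped, all different)
            for lab in counted:
                areas[lab] += share / len(counted)
    out = {c: areas[c] / 100.0 for c in _CLASSES}
    out["mapped"] = sum(out[c] for c in _CLASSES)
    out["total"] = float(fa.sum()) / 100.0
    return out


def analyze_eam(study: EAMStudy) -> tuple[VoltageClassMap, dict[str, float]]:
    """Interpolate, classify and measure scar areas for one study."""
    vmap = interpolate_voltage(study)
    return vmap, class_areas(vmap)
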