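"""Synthetic electroanatomic voltage maps with known scar-area ground truth.

An LV-like closed ellipsoidal surface carries mapping points at its mesh
vertices (guaranteeing the filling-density rule).  Scar patches are compact
vertex sets around configurable centers; bipolar amplitudes are drawn per
voltage class in the patch core (dense scar <= 0.5 mV, heterogeneous tissue
0.5-1.5 mV, healthy > 1.5 mV) and follow a deterministic rim profile -- a
steep ramp through the class threshold flanked by plateaus value-symmetric
about it -- so the interpolated threshold crossing, and hence the measured
patch area, sits at the patch radius on any mesh resolution.  Ground-truth
classes come from the amplitudes themselves and ground-truth class areas
apply the same mixed-triangle area rule, so the only thing under test
downstream is the amplitude interpolation + thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..eam import EAMStudy, VoltageClassMap, class_areas, classify_amplitude

__all__ = ["EAMPatch", "SyntheticEAMSpec", "SyntheticEAMResult", "generate_eam"]

AMPLITUDE_RANGES_MV = {
    "DS": (0.05, 0.45),
    "HT": (0.6, 1.4),
    "healthy": (1.8, 6.0),
}


@dataclass(frozen=True)
class EAMPatch:
    """A scar patch: vertices within ``radius_mm`` of ``center`` (mm)."""

    center: tuple[float, float, float]
    radius_mm: float
    voltage_class: str  # "DS" or "HT"

    def __post_init__(self):
        if self.voltage_class not in ("DS", "HT"):
            raise ValueError("patch class must be 'DS' or 'HT'")
        if self.radius_mm <= 0:
            raise ValueError("patch radius must be > 0")


@dataclass
class SyntheticEAMSpec:
    """Parameters of one synthetic voltage map."""

    mesh: object = None  # (vertices, faces); default LV-like ellipsoid
    subdivisions: int = 3
    semi_axes_mm: tuple[float, float, float] = (25.0, 25.0, 35.0)
    point_spacing: float = 5.0
    #: half-width of the deterministic amplitude ramp at each patch rim; the
    #: ramp is flanked by plateaus value-symmetric about the class threshold
    #: out to the fill radius, which pins the interpolated threshold crossing
    #: to the patch radius so measured areas are stable under mesh refinement
    transition_mm: float = 2.0
    scar_patches: list[EAMPatch] = field(default_factory=list)
    #: optional region whose points are withheld (simulates incomplete
    #: catheter coverage); vertices far from every point become unmapped
    unmapped_patch: EAMPatch | None = None
    amplitude_ranges: dict = field(default_factory=lambda: dict(AMPLITUDE_RANGES_MV))
    seed: int = 0

    def build_mesh(self):
        if self.mesh is not None:
            v, f = self.mesh
            v = np.asarray(v, dtype=float)
            f = np.asarray(f, dtype=int)
        else:
            import trimesh

            sphere = trimesh.creation.icosphere(subdivisions=self.subdivisions)
            v = sphere.vertices * np.asarray(self.semi_axes_mm)
            f = np.asarray(sphere.faces, dtype=int)
        if len(v) == 0 or len(f) == 0:
            raise ValueError("mesh must be nonempty")
        return v, f


@dataclass
class SyntheticEAMResult:
    study: EAMStudy
    gt_vertex_class: np.ndarray  # per-vertex class incl. "unmapped"
    gt_areas: dict[str, float]
    gt_map: VoltageClassMap


def generate_eam(spec: SyntheticEAMSpec) -> SyntheticEAMResult:
    """Build one voltage-map study with ground-truth classes and areas."""
    rng = np.random.default_rng(spec.seed)
    vertices, faces = spec.build_mesh()
    n = len(vertices)

    healthy_lo = spec.amplitude_ranges["healthy"][0]
    amplitudes = rng.uniform(*spec.amplitude_ranges["healthy"], size=n)
    T = spec.transition_mm
    F = spec.point_spacing
    # plateau values symmetric about the class threshold: inverse-distance
    # smoothing then leaves the interpolated threshold crossing at d = r
    profiles = {"DS": (0.5, 0.3), "HT": (1.5, 0.3)}
    for patch in spec.scar_patches:
        lo, hi = spec.amplitude_ranges[patch.voltage_class]
        threshold, half_step = profiles[patch.voltage_class]
        inner_val = threshold - half_step
        outer_val = threshold + half_step
        d = np.linalg.norm(vertices - np.asarray(patch.center), axis=1)
        r = patch.radius_mm
        patch_amp = np.full(n, np.inf)
        core = d <= r - F
        patch_amp[core] = rng.uniform(lo, hi, size=int(core.sum()))
        inner = (d > r - F) & (d <= r - T)
        patch_amp[inner] = inner_val
        ramp = (d > r - T) & (d <= r + T)
        patch_amp[ramp] = threshold + half_step * (d[ramp] - r) / T
        outer = (d > r + T) & (d <= r + F)
        patch_amp[outer] = outer_val
        rise = (d > r + F) & (d < r + F + 2 * T)
        patch_amp[rise] = outer_val + (healthy_lo - outer_val) * (
            d[rise] - r - F
        ) / (2 * T)
        amplitudes = np.minimum(amplitudes, patch_amp)
    vertex_class = np.asarray(classify_amplitude(amplitudes), dtype=object)

    keep = np.ones(n, dtype=bool)
    if spec.unmapped_patch is not None:
        d = np.linalg.norm(
            vertices - np.asarray(spec.unmapped_patch.center), axis=1
        )
        keep &= d > spec.unmapped_patch.radius_mm
    if not keep.any():
        raise ValueError("unmapped patch removes every mapping point")

    study = EAMStudy(
        points=vertices[keep],
        amplitudes=amplitudes[keep],
        vertices=vertices,
        faces=faces,
        fill_threshold=spec.point_spacing,
    )

    # ground truth: known classes, with nodes beyond the fill radius of the
    # retained points marked unmapped, measured by the same area rule
    gt_class = vertex_class.copy()
    if spec.unmapped_patch is not None:
        from scipy.spatial import cKDTree

        d_near, _ = cKDTree(vertices[keep]).query(vertices)
        gt_class[d_near > spec.point_spacing] = "unmapped"
    gt_map = VoltageClassMap(
        vertices=vertices,
        faces=faces,
        amplitude=np.where(gt_class != "unmapped", amplitudes, np.nan),
        node_class=gt_class,
    )
    return SyntheticEAMResult(
        study=study,
        gt_vertex_class=gt_class,
        gt_areas=class_areas(gt_map),
        gt_map=gt_map,
    )
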