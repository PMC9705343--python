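"""Late-gadolinium-enhancement scar mapping and quantification.

The workflow mirrors signal-intensity scar mapping on short-axis LGE-CMR:

1. voxel intensities are expressed in z units, i.e. standard deviations of a
   remote healthy-myocardium reference ROI (``normalize_to_sd_units``);
2. the wall between the endo- and epicardial contours is split into an inner
   and an outer half by distance to the bounding contours
   (``split_wall_halves``);
3. the mean z of each half is projected onto the corresponding contour
   surface and every surface node is classified as healthy myocardium (HM,
   z < 2), heterogeneous tissue (HT, 2 <= z < 3) or dense scar (DS, z >= 3)
   (``project_half_wall_si``);
4. compartment areas (EnHT, EnDS, EpHT, EpDS), scar and myocardial masses,
   and ventricular volumes are tallied (``quantify``), and longitudinal
   remodeling is expressed as relative percentage change
   (``percent_change``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LinearRing, Polygon

__all__ = [
    "LGEVolume",
    "WallContours",
    "WallMasks",
    "ZVolume",
    "WallSurface",
    "SurfaceSIMap",
    "ScarQuantification",
    "HT_THRESHOLD_SD",
    "DS_THRESHOLD_SD",
    "MYOCARDIAL_DENSITY_G_PER_ML",
    "classify_tissue",
    "split_wall_halves",
    "normalize_to_sd_units",
    "build_wall_surface",
    "project_half_wall_si",
    "simpson_volume_ml",
    "quantify",
    "percent_change",
]

HT_THRESHOLD_SD = 2.0  #: z >= 2 is scar (heterogeneous tissue)
DS_THRESHOLD_SD = 3.0  #: z >= 3 is dense scar
MYOCARDIAL_DENSITY_G_PER_ML = 1.05  # standard CMR mass convention


@dataclass
class LGEVolume:
    """A 3-D LGE intensity volume.

    ``data`` is indexed ``[ix, iy, islice]``; voxel centers sit at
    ``(i + 0.5) * voxel_size`` (0-based indices, half-open voxel extents,
    world units in mm).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    slice_axis: int = 2

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be strictly positive")
        if not np.isfinite(self.data).all():
            raise ValueError("intensities must be finite")
        if self.slice_axis != 2:
            raise ValueError("slice axis must be the last axis")

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0


class WallContours:
    """Per-slice closed endo/epi polygons in mm.

    Stored as ``{slice_index: {"endo": (K,2) array, "epi": (K,2) array}}``;
    polygons must be simple (non-self-intersecting) and the endocardial
    polygon strictly inside the epicardial one.
    """

    def __init__(self, contours: dict[int, dict[str, np.ndarray]]):
        self._contours = {}
        for s, d in contours.items():
            entry = {}
            for surf in ("endo", "epi"):
                poly = np.asarray(d[surf], dtype=float)
                if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                    raise ValueError(f"slice {s} {surf}: need a (K>=3, 2) polygon")
                entry[surf] = poly
            if not Polygon(entry["epi"]).contains(Polygon(entry["endo"])):
                raise ValueError(
                    f"slice {s}: endocardial contour not inside epicardial contour"
                )
            self._contours[int(s)] = entry

    @property
    def slices(self) -> list[int]:
        return sorted(self._contours)

    def polygon(self, slice_index: int, surface: str) -> np.ndarray:
        return self._contours[slice_index][surface]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for s in self.slices:
            for surf in ("endo", "epi"):
                for x, y in self._contours[s][surf]:
                    rows.append(
                        {"slice_index": s, "surface": surf, "x_mm": x, "y_mm": y}
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df) -> "WallContours":
        contours: dict[int, dict[str, np.ndarray]] = {}
        for (s, surf), grp in df.groupby(["slice_index", "surface"], sort=True):
            contours.setdefault(int(s), {})[str(surf)] = grp[
                ["x_mm", "y_mm"]
            ].to_numpy()
        return cls(contours)


@dataclass
class WallMasks:
    """Boolean wall partition: ``endo_half | epi_half == wall``, disjoint."""

    wall: np.ndarray
    endo_half: np.ndarray
    epi_half: np.ndarray


@dataclass
class ZVolume:
    """Per-voxel signal intensity in remote-SD units, with the wall partition.

    ``z`` is NaN outside the wall.
    """

    z: np.ndarray
    masks: WallMasks
    remote_mean: float
    remote_sd: float
    voxel_size: tuple[float, float, float]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0


def classify_tissue(z):
    """Classify z-scored signal intensity into HM / HT / DS.

    z < 2 is healthy myocardium (HM); 2 <= z < 3 heterogeneous tissue (HT);
    z >= 3 dense scar (DS).  Accepts scalars or arrays; all values must be
    finite.
    """
    arr = np.asarray(z, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("z values must be finite")
    out = np.select(
        [arr >= DS_THRESHOLD_SD, arr >= HT_THRESHOLD_SD], ["DS", "HT"], default="HM"
    )
    return str(out[()]) if np.isscalar(z) or arr.ndim == 0 else out


def _voxel_center_grid(shape, voxel_size):
    nx, ny = shape[0], shape[1]
    dx, dy = voxel_size[0], voxel_size[1]
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    gx, gy = np.meshgrid(x, y, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def split_wall_halves(contours: WallContours, volume: LGEVolume) -> WallMasks:
    """Partition wall voxels into the endocardial and epicardial halves.

    A voxel belongs to the wall when its center lies inside the epicardial
    and outside the endocardial polygon of its slice.  It is assigned to the
    half whose bounding contour is nearer (in-plane distance); equidistant
    voxels go to the endocardial half.
    """
    shape = volume.data.shape
    wall = np.zeros(shape, dtype=bool)
    endo_half = np.zeros(shape, dtype=bool)
    pts2d = _voxel_center_grid(shape, volume.voxel_size)
    points = shapely.points(pts2d)

    cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
    for s in contours.slices:
        if s < 0 or s >= shape[2]:
            continue
        endo_xy = contours.polygon(s, "endo")
        epi_xy = contours.polygon(s, "epi")
        key = endo_xy.tobytes() + epi_xy.tobytes()
        if key not in cache:  # stacks often repeat identical contours
            in_wall = shapely.contains(Polygon(epi_xy), points) & ~shapely.contains(
                Polygon(endo_xy), points
            )
            d_endo = shapely.distance(points, LinearRing(endo_xy))
            d_epi = shapely.distance(points, LinearRing(epi_xy))
            cache[key] = (
                in_wall.reshape(shape[:2]),
                (in_wall & (d_endo <= d_epi)).reshape(shape[:2]),
            )
        wall[:, :, s], endo_half[:, :, s] = cache[key]

    epi_half = wall & ~endo_half
    return WallMasks(wall=wall, endo_half=endo_half, epi_half=epi_half)


def normalize_to_sd_units(
    volume: LGEVolume,
    remote_roi: np.ndarray,
    masks: WallMasks,
    *,
    declared_scar: np.ndarray | None = None,
    min_roi_voxels: int = 30,
) -> ZVolume:
    """Express wall intensities in standard deviations of a remote ROI.

    ``z = (I - mean_remote) / sd_remote`` for wall voxels, NaN elsewhere.

    Raises when the ROI is too small or (near-)constant, which would make
    the normalization degenerate; warns when the ROI overlaps a declared
    scar mask.
    """
    remote_roi = np.asarray(remote_roi, dtype=bool)
    if remote_roi.shape != volume.data.shape:
        raise ValueError("remote ROI shape must match the volume")
    n_roi = int(remote_roi.sum())
    if n_roi < min_roi_voxels:
        raise ValueError(f"remote ROI has {n_roi} voxels; need >= {min_roi_voxels}")
    vals = volume.data[remote_roi]
    mu = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd <= 1e-9 * max(abs(mu), 1.0):
        raise ValueError("remote ROI standard deviation is (near) zero")
    if declared_scar is not None and np.any(remote_roi & np.asarray(declared_scar, bool)):
        warnings.warn("remote ROI overlaps declared scar voxels", stacklevel=2)

    z = np.full(volume.data.shape, np.nan)
    z[masks.wall] = (volume.data[masks.wall] - mu) / sd
    return ZVolume(
        z=z,
        masks=masks,
        remote_mean=mu,
        remote_sd=sd,
        voxel_size=volume.voxel_size,
    )


@dataclass
class WallSurface:
    """Triangulated contour-stack surface.

    Nodes are sampled at ``n_theta`` equal angles on every slice contour
    (radius interpolated by polar angle around the slice centroid, valid for
    star-shaped contours) and adjacent rings are stitched with triangles.
    ``node_area_mm2`` is the barycentric node area: one third of the summed
    incident triangle areas.
    """

    nodes: np.ndarray  # (N, 3) mm
    faces: np.ndarray  # (M, 3) int
    node_area_mm2: np.ndarray  # (N,)
    surface: str  # "endo" or "epi"
    n_theta: int = 0
    ring_of_slice: dict = None  # slice index -> ring index
    ring_centers: np.ndarray = None  # (R, 2) in-plane contour centroids
    cap_rings: tuple = ()  # (first cap ring, last cap ring) indices

    @property
    def total_area_cm2(self) -> float:
        return float(self.node_area_mm2.sum()) / 100.0


def _resample_ring(poly: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Points on a star-shaped closed polygon at given polar angles."""
    c = poly.mean(axis=0)
    rel = poly - c
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    rad = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(ang)
    ang, rad = ang[order], rad[order]
    ang_ext = np.concatenate([ang, ang[:1] + 2 * np.pi])
    rad_ext = np.concatenate([rad, rad[:1]])
    t = np.mod(thetas - ang[0], 2 * np.pi) + ang[0]
    r = np.interp(t, ang_ext, rad_ext)
    return c + np.column_stack([r * np.cos(thetas), r * np.sin(thetas)])


def build_wall_surface(
    contours: WallContours,
    volume: LGEVolume,
    surface: str,
    *,
    n_theta: int = 64,
) -> WallSurface:
    """Build the endo- or epicardial surface mesh from the contour stack."""
    if surface not in ("endo", "epi"):
        raise ValueError("surface must be 'endo' or 'epi'")
    dz = volume.voxel_size[2]
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    rings = []
    centers = []
    slices = contours.slices
    for s in slices:
        ring2d = _resample_ring(contours.polygon(s, surface), thetas)
        z = (s + 0.5) * dz
        rings.append(np.column_stack([ring2d, np.full(n_theta, z)]))
        centers.append(contours.polygon(s, surface).mean(axis=0))
    # boundary rings close the half-slice gaps at the stack ends so the
    # surface spans the full covered wall height
    first = _resample_ring(contours.polygon(slices[0], surface), thetas)
    last = _resample_ring(contours.polygon(slices[-1], surface), thetas)
    rings.insert(0, np.column_stack([first, np.full(n_theta, slices[0] * dz)]))
    rings.append(np.column_stack([last, np.full(n_theta, (slices[-1] + 1) * dz)]))
    centers = [centers[0]] + centers + [centers[-1]]
    nodes = np.concatenate(rings, axis=0)
    ring_of_slice = {s: k + 1 for k, s in enumerate(slices)}

    faces = []
    for b in range(len(rings) - 1):
        lo, hi = b * n_theta, (b + 1) * n_theta
        for j in range(n_theta):
            k = (j + 1) % n_theta
            faces.append([lo + j, lo + k, hi + j])
            faces.append([lo + k, hi + k, hi + j])
    faces = np.asarray(faces, dtype=int)

    import trimesh

    mesh = trimesh.Trimesh(vertices=nodes, faces=faces, process=False)
    node_area = np.zeros(len(nodes))
    np.add.at(node_area, faces.ravel(), np.repeat(mesh.area_faces / 3.0, 3))
    return WallSurface(
        nodes=nodes,
        faces=faces,
        node_area_mm2=node_area,
        surface=surface,
        n_theta=n_theta,
        ring_of_slice=ring_of_slice,
        ring_centers=np.asarray(centers),
        cap_rings=(0, len(rings) - 1),
    )


@dataclass
class SurfaceSIMap:
    """Per-node half-wall mean signal intensity (SD units) and tissue label.

    Unmapped nodes (no wall voxel assigned) carry NaN SI, label
    ``"unmapped"`` and are excluded from all area sums.
    """

    surface: WallSurface
    si_sd: np.ndarray
    label: np.ndarray
    valid: np.ndarray
    half: str  # "endo" or "epi"

    def area_cm2(self, label: str) -> float:
        sel = self.valid & (self.label == label)
        return float(self.surface.node_area_mm2[sel].sum()) / 100.0

    @property
    def areas_cm2(self) -> dict[str, float]:
        return {lab: self.area_cm2(lab) for lab in ("HM", "HT", "DS")}

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node_id": np.arange(len(self.si_sd)),
                "si_sd": self.si_sd,
                "label": self.label,
                "area_cm2": self.surface.node_area_mm2 / 100.0,
            }
        )


def project_half_wall_si(
    zvol: ZVolume, half_mask: np.ndarray, surface: WallSurface
) -> SurfaceSIMap:
    """Project the mean half-wall z onto the bounding surface.

    Every voxel of the half is assigned to the node on the transmural ray
    through it: the node of its own slice's contour ring at the nearest
    polar angle around the contour centroid.  Each node's SI is the mean z
    of its voxels and its label follows the 2/3-SD rule.  The stack-end cap
    rings inherit SI from their adjacent slice ring; nodes with no voxels
    are flagged unmapped and excluded from areas.
    """
    half_mask = np.asarray(half_mask, dtype=bool)
    idx = np.argwhere(half_mask & np.isfinite(zvol.z))
    n_nodes = len(surface.nodes)
    nt = surface.n_theta
    si = np.full(n_nodes, np.nan)
    label = np.full(n_nodes, "unmapped", dtype=object)
    valid = np.zeros(n_nodes, dtype=bool)
    if len(idx):
        in_ring = np.array([surface.ring_of_slice.get(s, -1) for s in idx[:, 2]])
        keep = in_ring >= 0
        idx, in_ring = idx[keep], in_ring[keep]
        cxy = (idx[:, :2] + 0.5) * np.asarray(zvol.voxel_size[:2])
        rel = cxy - surface.ring_centers[in_ring]
        theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
        k = np.rint(theta / (2 * np.pi / nt)).astype(int) % nt
        node_of = in_ring * nt + k
        zvals = zvol.z[tuple(idx.T)]
        sums = np.bincount(node_of, weights=zvals, minlength=n_nodes)
        counts = np.bincount(node_of, minlength=n_nodes)
        mapped = counts > 0
        si[mapped] = sums[mapped] / counts[mapped]
        # caps mirror the adjacent slice ring
        first_cap, last_cap = surface.cap_rings
        n_rings = n_nodes // nt
        for cap, src in ((first_cap, 1), (last_cap, n_rings - 2)):
            cs = slice(cap * nt, (cap + 1) * nt)
            ss = slice(src * nt, (src + 1) * nt)
            si[cs] = si[ss]
            mapped[cs] = mapped[ss]
        ok = mapped & np.isfinite(si)
        label[ok] = classify_tissue(si[ok])
        valid = ok
    half = "endo" if surface.surface == "endo" else "epi"
    return SurfaceSIMap(
        surface=surface, si_sd=si, label=np.asarray(label, dtype=object),
        valid=valid, half=half,
    )


@dataclass
class ScarQuantification:
    """Study-level scar summary.

    Areas in cm2, masses in g, volumes in ml, LVEF in percent.  Volumes are
    ``None`` when no cine contours were supplied.
    """

    EnDS: float
    EnHT: float
    EpDS: float
    EpHT: float
    TSM: float
    TMM: float
    LVEDV: float | None = None
    LVESV: float | None = None
    LVEF: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "EnDS_cm2": self.EnDS,
            "EnHT_cm2": self.EnHT,
            "EpDS_cm2": self.EpDS,
            "EpHT_cm2": self.EpHT,
            "TSM_g": self.TSM,
            "TMM_g": self.TMM,
            "LVEDV_ml": self.LVEDV,
            "LVESV_ml": self.LVESV,
            "LVEF_pct": self.LVEF,
        }


def simpson_volume_ml(contours: WallContours, volume: LGEVolume, surface: str = "endo") -> float:
    """Cavity (or epicardial) volume by slice-area summation (Simpson)."""
    dz = volume.voxel_size[2]
    total_mm3 = sum(
        Polygon(contours.polygon(s, surface)).area * dz for s in contours.slices
    )
    return float(total_mm3) / 1000.0


def quantify(
    map_endo: SurfaceSIMap,
    map_epi: SurfaceSIMap,
    zvol: ZVolume,
    *,
    ed_contours: WallContours | None = None,
    es_contours: WallContours | None = None,
    lge_volume: LGEVolume | None = None,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> ScarQuantification:
    """Tally compartment areas, masses and (optionally) volumes.

    Scar mass is volumetric: every wall voxel with z >= 2 counts toward TSM
    regardless of the surface labels; TMM is the whole wall.  LVEDV/LVESV
    come from Simpson summation of the endocardial contours at the two cine
    phases when supplied; otherwise the volume fields stay ``None``.
    """
    if map_endo.half != "endo" or map_epi.half != "epi":
        raise ValueError("pass the endocardial map first and the epicardial second")
    wall = zvol.masks.wall
    scar_voxels = int(np.count_nonzero(zvol.z[wall] >= HT_THRESHOLD_SD))
    tsm = scar_voxels * zvol.voxel_volume_ml * density_g_per_ml
    tmm = int(wall.sum()) * zvol.voxel_volume_ml * density_g_per_ml

    lvedv = lvesv = lvef = None
    if ed_contours is not None and es_contours is not None:
        if lge_volume is None:
            raise ValueError("cine volume geometry needed for Simpson volumes")
        lvedv = simpson_volume_ml(ed_contours, lge_volume, "endo")
        lvesv = simpson_volume_ml(es_contours, lge_volume, "endo")
        if lvedv <= 0:
            raise ValueError("end-diastolic volume must be positive")
        lvef = 100.0 * (lvedv - lvesv) / lvedv

    return ScarQuantification(
        EnDS=map_endo.area_cm2("DS"),
        EnHT=map_endo.area_cm2("HT"),
        EpDS=map_epi.area_cm2("DS"),
        EpHT=map_epi.area_cm2("HT"),
        TSM=tsm,
        TMM=tmm,
        LVEDV=lvedv,
        LVESV=lvesv,
        LVEF=lvef,
    )


def percent_change(baseline: float, followup: float) -> float:
    """Relative change from baseline, in percent: 100*(followup-baseline)/baseline."""
    if baseline == 0:
        raise ValueError("percentage change is undefined for a zero baseline")
    return 100.0 * (followup - baseline) / baseline
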