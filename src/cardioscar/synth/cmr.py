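"""Synthetic LGE-CMR phantoms with known scar ground truth.

The phantom is an annular (circle-in-circle) left-ventricular wall stacked
over short-axis slices.  Remote-myocardium voxels carry Gaussian texture
whose sample mean and SD over the designated remote ROI are *exactly* the
configured values, so z-scoring against that ROI reproduces configured scar
offsets exactly in the noiseless case.  Scar regions are angular sectors
over a slice range confined to the endocardial half, epicardial half, or
the full wall thickness, with intensity offsets expressed in remote-SD
units (an offset >= 2 reads as heterogeneous tissue, >= 3 as dense scar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..cmr import (
    DS_THRESHOLD_SD,
    HT_THRESHOLD_SD,
    LGEVolume,
    WallContours,
    WallMasks,
    split_wall_halves,
)

__all__ = ["ScarRegion", "SyntheticCMRSpec", "SyntheticCMRResult", "generate_cmr"]

COMPARTMENTS = ("endo", "epi", "transmural")


@dataclass(frozen=True)
class ScarRegion:
    """An angular scar sector.

    ``theta_start_deg``/``theta_end_deg`` delimit the sector (counter-
    clockwise, wrap-around allowed); ``slice_start``/``slice_stop`` are a
    half-open slice range; ``compartment`` selects the transmural extent;
    ``offset_sd`` is the intensity elevation above remote mean in remote-SD
    units.
    """

    theta_start_deg: float
    theta_end_deg: float
    slice_start: int
    slice_stop: int
    compartment: str
    offset_sd: float

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        if self.offset_sd < 0:
            raise ValueError("scar intensity offsets must be >= 0")

    def contains_angle(self, theta_deg: np.ndarray) -> np.ndarray:
        a = self.theta_start_deg % 360.0
        b = self.theta_end_deg % 360.0
        th = theta_deg % 360.0
        if a <= b:
            return (th >= a) & (th < b)
        return (th >= a) | (th < b)


@dataclass
class SyntheticCMRSpec:
    """Parameters of one LGE phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 6)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 5.0)
    #: per-slice (endo_radius, epi_radius) in mm; a single pair applies to
    #: every slice
    wall_geometry: object = (14.0, 22.0)
    remote_mean: float = 100.0
    remote_sd: float = 10.0
    scar_regions: list[ScarRegion] = field(default_factory=list)
    noise_sd: float = 0.0
    background: float = 10.0
    #: angular clearance between scar sectors and the remote ROI
    remote_margin_deg: float = 10.0
    n_contour_points: int = 72
    seed: int = 0

    def radii(self) -> list[tuple[float, float]]:
        wg = self.wall_geometry
        if isinstance(wg, tuple) and np.isscalar(wg[0]):
            wg = [wg] * self.grid_shape[2]
        wg = [tuple(map(float, p)) for p in wg]
        if len(wg) != self.grid_shape[2]:
            raise ValueError("wall_geometry must give radii for every slice")
        return wg

    def validate(self):
        if self.remote_sd <= 0:
            raise ValueError("remote_sd must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        nx, ny, ns = self.grid_shape
        half_extent = 0.5 * min(nx * self.voxel_size[0], ny * self.voxel_size[1])
        for s, (r_endo, r_epi) in enumerate(self.radii()):
            if not r_endo < r_epi:
                raise ValueError(
                    f"slice {s}: endo radius {r_endo} must be < epi radius {r_epi}"
                )
            if r_epi >= half_extent:
                raise ValueError(f"slice {s}: epicardial radius exceeds the grid")
        for reg in self.scar_regions:
            if not (0 <= reg.slice_start < reg.slice_stop <= ns):
                raise ValueError("scar region slice range outside the volume")


@dataclass
class SyntheticCMRResult:
    """Phantom plus ground truth."""

    volume: LGEVolume
    contours: WallContours
    labels: np.ndarray  # per-voxel "BG"/"HM"/"HT"/"DS"
    masks: WallMasks
    remote_roi: np.ndarray
    offsets_sd: np.ndarray  # per-voxel configured offset (0 outside scar)


def _circle(center, radius, n) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


def generate_cmr(spec: SyntheticCMRSpec) -> SyntheticCMRResult:
    """Build one phantom: volume, contours, labels, wall masks, remote ROI.

    Identical spec and seed give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, ns = spec.grid_shape
    dx, dy, dz = spec.voxel_size
    center = (0.5 * nx * dx, 0.5 * ny * dy)

    contours = WallContours(
        {
            s: {
                "endo": _circle(center, r_endo, spec.n_contour_points),
                "epi": _circle(center, r_epi, spec.n_contour_points),
            }
            for s, (r_endo, r_epi) in enumerate(spec.radii())
        }
    )
    geom = LGEVolume(np.zeros(spec.grid_shape), spec.voxel_size)
    masks = split_wall_halves(contours, geom)

    x = (np.arange(nx) + 0.5) * dx - center[0]
    y = (np.arange(ny) + 0.5) * dy - center[1]
    gx, gy = np.meshgrid(x, y, indexing="ij")
    theta = np.degrees(np.arctan2(gy, gx)) % 360.0  # (nx, ny)

    offsets = np.zeros(spec.grid_shape)
    for reg in spec.scar_regions:
        comp_mask = {
            "endo": masks.endo_half,
            "epi": masks.epi_half,
            "transmural": masks.wall,
        }[reg.compartment]
        sector = reg.contains_angle(theta)
        region = np.zeros(spec.grid_shape, dtype=bool)
        region[:, :, reg.slice_start : reg.slice_stop] = sector[:, :, None]
        region &= comp_mask
        offsets[region] = np.maximum(offsets[region], reg.offset_sd)

    labels = np.full(spec.grid_shape, "BG", dtype=object)
    labels[masks.wall] = "HM"
    labels[masks.wall & (offsets >= HT_THRESHOLD_SD)] = "HT"
    labels[masks.wall & (offsets >= DS_THRESHOLD_SD)] = "DS"

    # remote ROI: healthy wall voxels angularly clear of every scar sector
    clear = np.ones((nx, ny), dtype=bool)
    for reg in spec.scar_regions:
        widened = ScarRegion(
            reg.theta_start_deg - spec.remote_margin_deg,
            reg.theta_end_deg + spec.remote_margin_deg,
            reg.slice_start,
            reg.slice_stop,
            "transmural",
            0.0,
        )
        clear &= ~widened.contains_angle(theta)
    remote_roi = masks.wall & (labels == "HM") & clear[:, :, None]

    intensities = np.full(spec.grid_shape, float(spec.background))
    hm_wall = masks.wall & (offsets == 0)
    texture = rng.standard_normal(int(hm_wall.sum()))
    # standardize the ROI subset so its sample stats are exactly the spec's
    roi_in_hm = remote_roi[hm_wall]
    if roi_in_hm.any():
        sub = texture[roi_in_hm]
        sd = sub.std(ddof=1)
        if sd > 0:
            texture[roi_in_hm] = (sub - sub.mean()) / sd
    intensities[hm_wall] = spec.remote_mean + spec.remote_sd * texture
    scar = masks.wall & (offsets > 0)
    intensities[scar] = spec.remote_mean + spec.remote_sd * offsets[scar]
    if spec.noise_sd > 0:
        intensities = intensities + spec.noise_sd * rng.standard_normal(
            spec.grid_shape
        )

    volume = LGEVolume(intensities, spec.voxel_size)
    return SyntheticCMRResult(
        volume=volume,
        contours=contours,
        labels=labels,
        masks=masks,
        remote_roi=remote_roi,
        offsets_sd=offsets,
    )
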