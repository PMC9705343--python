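"""Synthetic voltage-dye movies with closed-form electrophysiology ground truth.

A paced wavefront travels from an edge or point origin across a pixel grid;
travel times are slowness-weighted shortest paths (fast-marching style), so
a slow heterogeneous-tissue (HT) patch bends the isochrones.  Each pixel's
trace is a stereotyped action potential shifted by its travel time and
repeated every pacing cycle; the template is built so that

* the instant of maximal upstroke slope is exactly the travel time, and
* the 80 %-repolarization crossing is exactly APD80 after it,

making activation, APD80 and conduction velocity ground truth closed-form.
The dye polarity is inverted by default (fluorescence falls on
depolarization), forcing downstream preprocessing to handle the sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..optical import ActivationMap, APDMap, CVField, OpticalRecording, ROISet

__all__ = [
    "APTemplate",
    "SyntheticOpticalSpec",
    "OpticalGroundTruth",
    "SyntheticOpticalResult",
    "disk_mask",
    "generate_optical",
]

#: phase (fraction of the repolarization half-cosine) at which the
#: normalized template crosses 0.2: solve 0.5*(1+cos(pi*s)) = 0.2
_CROSS_FRACTION = float(np.arccos(-0.6) / np.pi)


@dataclass(frozen=True)
class APTemplate:
    """Stereotyped optical action potential.

    Linear upstroke of ``upstroke_ms`` centered on the activation instant,
    then a half-cosine repolarization scaled so the 20 %-amplitude crossing
    falls exactly ``apd80_ms`` after activation.
    """

    amplitude: float = 1000.0  # counts
    apd80_ms: float = 200.0
    upstroke_ms: float = 2.0

    def __post_init__(self):
        if self.amplitude <= 0 or self.apd80_ms <= 0 or self.upstroke_ms < 0:
            raise ValueError("template parameters must be positive")
        if self.apd80_ms <= self.upstroke_ms:
            raise ValueError("apd80 must exceed the upstroke duration")

    def repol_tau_ms(self, apd80_ms: float | None = None) -> float:
        apd = self.apd80_ms if apd80_ms is None else apd80_ms
        return (apd - 0.5 * self.upstroke_ms) / _CROSS_FRACTION

    def waveform(self, t_ms: np.ndarray, apd80_ms: float | None = None) -> np.ndarray:
        """Normalized template value at time ``t_ms`` relative to activation."""
        t = np.asarray(t_ms, dtype=float)
        half_up = 0.5 * self.upstroke_ms
        tau = self.repol_tau_ms(apd80_ms)
        v = np.zeros_like(t)
        if self.upstroke_ms > 0:
            rising = (t >= -half_up) & (t < half_up)
            v[rising] = (t[rising] + half_up) / self.upstroke_ms
        else:
            rising = np.zeros_like(t, dtype=bool)
        falling = (t >= half_up) & (t < half_up + tau)
        v[falling] = 0.5 * (1.0 + np.cos(np.pi * (t[falling] - half_up) / tau))
        return v


@dataclass
class SyntheticOpticalSpec:
    """Parameters of one synthetic pacing recording."""

    grid_shape: tuple[int, int] = (128, 128)  # (H, W) pixels
    pixel_size: float = 0.5  # mm
    frame_interval: float = 1.0  # ms
    n_beats: int = 3
    cycle_length: float = 600.0  # ms
    ap_template: APTemplate = field(default_factory=APTemplate)
    hm_velocity_cm_s: float = 50.0
    ht_mask: np.ndarray | None = None
    ht_velocity_ratio: float = 0.55
    ht_apd_ratio: float = 1.3
    wave_origin: object = "edge:left"  # or ("point", (row, col))
    noise_sd: float = 0.0
    invert_polarity: bool = True
    baseline_counts: float = 3000.0
    first_stimulus_ms: float = 5.0
    seed: int = 0

    def validate(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0 or self.hm_velocity_cm_s <= 0:
            raise ValueError("pixel size and velocity must be > 0")
        if self.ht_velocity_ratio <= 0 or self.ht_apd_ratio <= 0:
            raise ValueError("HT ratios must be > 0")
        if self.n_beats < 1:
            raise ValueError("need at least one beat")
        apds = [self.ap_template.apd80_ms, self.ap_template.apd80_ms * self.ht_apd_ratio]
        if self.cycle_length <= max(apds) + self.ap_template.upstroke_ms:
            raise ValueError("cycle length must exceed the longest APD")
        if self.ht_mask is not None:
            m = np.asarray(self.ht_mask, dtype=bool)
            if m.shape != tuple(self.grid_shape):
                raise ValueError("ht_patch mask must match the pixel grid")
        if isinstance(self.wave_origin, tuple):
            kind, (r, c) = self.wave_origin
            h, w = self.grid_shape
            if kind != "point" or not (0 <= r < h and 0 <= c < w):
                raise ValueError("point origin outside the grid")
        elif self.wave_origin not in ("edge:left", "edge:top"):
            raise ValueError("wave_origin must be 'edge:left', 'edge:top' or ('point', (r, c))")


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    """Disk ROI fully inside the grid; raises when it spills over the edge."""
    h, w = shape
    r0, c0 = center
    if (
        r0 - radius_px < 0
        or c0 - radius_px < 0
        or r0 + radius_px > h - 1
        or c0 + radius_px > w - 1
    ):
        raise ValueError("ht_patch disk extends outside the pixel grid")
    rr, cc = np.mgrid[0:h, 0:w]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2


@dataclass
class OpticalGroundTruth:
    """Construction-time truth for one recording."""

    travel_time_ms: np.ndarray  # = activation time per pixel
    activation: ActivationMap
    apd: APDMap
    cv: CVField
    ht_mask: np.ndarray

    def rois(self, margin_px: int = 3) -> ROISet:
        """Eroded HT mask vs. dilated-complement HM mask, clear of the frame
        border, suitable for regional summaries free of boundary mixing."""
        from scipy.ndimage import binary_dilation, binary_erosion

        ht = self.ht_mask
        core = binary_erosion(ht, iterations=margin_px) if margin_px else ht
        far = ~binary_dilation(ht, iterations=2 * margin_px) if margin_px else ~ht
        border = np.zeros_like(ht)
        b = max(margin_px, 1)
        border[b:-b, b:-b] = True
        return ROISet(hm=far & border, ht=core & border)


@dataclass
class SyntheticOpticalResult:
    recording: OpticalRecording
    truth: OpticalGroundTruth
    spec: SyntheticOpticalSpec


def _travel_time(spec: SyntheticOpticalSpec) -> np.ndarray:
    """Slowness-weighted shortest-path travel time (ms) from the origin."""
    from skimage.graph import MCP_Geometric

    h, w = spec.grid_shape
    v = np.full((h, w), spec.hm_velocity_cm_s / 100.0)  # mm/ms
    if spec.ht_mask is not None:
        v[np.asarray(spec.ht_mask, bool)] *= spec.ht_velocity_ratio
    slowness = 1.0 / v  # ms/mm
    if spec.wave_origin == "edge:left":
        starts = [(i, 0) for i in range(h)]
    elif spec.wave_origin == "edge:top":
        starts = [(0, j) for j in range(w)]
    else:
        starts = [tuple(map(int, spec.wave_origin[1]))]
    mcp = MCP_Geometric(slowness, sampling=(spec.pixel_size, spec.pixel_size))
    costs, _ = mcp.find_costs(starts)
    return np.asarray(costs)


def generate_optical(spec: SyntheticOpticalSpec) -> SyntheticOpticalResult:
    """Build one movie plus activation/APD80/CV ground truth.

    Identical spec and seed give bit-identical frames.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.grid_shape
    dt = spec.frame_interval
    cl = spec.cycle_length
    tpl = spec.ap_template

    travel = _travel_time(spec)
    ht = (
        np.asarray(spec.ht_mask, bool)
        if spec.ht_mask is not None
        else np.zeros((h, w), dtype=bool)
    )
    apd_map = np.full((h, w), tpl.apd80_ms)
    apd_map[ht] = tpl.apd80_ms * spec.ht_apd_ratio
    speed_map = np.full((h, w), spec.hm_velocity_cm_s)
    speed_map[ht] = spec.hm_velocity_cm_s * spec.ht_velocity_ratio
    gy, gx = np.gradient(travel, spec.pixel_size)
    gnorm = np.hypot(gx, gy)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.stack([gx / gnorm, gy / gnorm], axis=-1)

    n_frames = int(np.ceil((spec.first_stimulus_ms + spec.n_beats * cl) / dt))
    t = np.arange(n_frames) * dt  # (F,)
    u = t[:, None, None] - spec.first_stimulus_ms - travel[None, :, :]
    half_up = 0.5 * tpl.upstroke_ms
    phase = np.where(u >= -half_up, np.mod(u + half_up, cl) - half_up, -np.inf)

    v = np.zeros_like(phase)
    for region, apd in ((~ht, tpl.apd80_ms), (ht, tpl.apd80_ms * spec.ht_apd_ratio)):
        if region.any():
            sub = phase[:, region]
            v[:, region] = tpl.waveform(sub, apd80_ms=apd)

    sign = -1.0 if spec.invert_polarity else 1.0
    frames = spec.baseline_counts + sign * tpl.amplitude * v
    if spec.noise_sd > 0:
        frames = frames + spec.noise_sd * rng.standard_normal(frames.shape)
    frames = np.clip(frames, 0.0, 65535.0)

    stim = spec.first_stimulus_ms + cl * np.arange(spec.n_beats)
    rec = OpticalRecording(
        frames=frames.astype(np.float32),
        frame_interval=dt,
        pixel_size=spec.pixel_size,
        stimulus_times=stim,
        cycle_length=cl,
    )
    ones = np.ones((h, w), dtype=bool)
    truth = OpticalGroundTruth(
        travel_time_ms=travel,
        activation=ActivationMap(
            times=travel.copy(), valid=ones.copy(), frame_interval=dt,
            pixel_size=spec.pixel_size,
        ),
        apd=APDMap(apd80=apd_map, valid=ones.copy()),
        cv=CVField(speed=speed_map, direction=direction, valid=ones.copy()),
        ht_mask=ht,
    )
    return SyntheticOpticalResult(recording=rec, truth=truth, spec=spec)
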