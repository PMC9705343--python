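"""Optical-mapping electrophysiology: activation, APD80 and conduction velocity.

A voltage-dye movie (nominally 128x128 pixels, 16 bit) recorded during drive
train pacing is turned into per-pixel maps:

* **activation time** — instant of maximal upstroke slope (dF/dt max) with
  quadratic sub-frame interpolation;
* **APD80** — action potential duration at 80 % repolarization: the first
  post-peak crossing of 20 % of the normalized amplitude, minus the
  activation time, with linear inter-frame interpolation;
* **conduction velocity** — from the spatial gradient of the activation
  map: a least-squares plane fit over a small window gives the local
  isochrone normal; speed is the reciprocal gradient magnitude.

Regional electrical heterogeneity between heterogeneous tissue (HT) and
healthy myocardium (HM) is summarized as 100*(HT - HM)/HM of the regional
medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalRecording",
    "ActivationMap",
    "APDMap",
    "CVField",
    "ROISet",
    "preprocess",
    "segment_beats",
    "detect_activation",
    "compute_apd80",
    "build_isochrones",
    "estimate_cv",
    "regional_relative_difference",
    "analyze_recording",
]

SPEED_CAP_CM_S = 200.0  # physiological cap; faster estimates are artifacts


@dataclass
class OpticalRecording:
    """A dye movie plus its acquisition sidecar.

    ``frames`` is (T, H, W); ``frame_interval`` in ms, ``pixel_size`` in mm,
    stimulus times in ms on the recording clock, pacing ``cycle_length`` in
    ms.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float
    stimulus_times: np.ndarray
    cycle_length: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame interval and pixel size must be positive")
        if self.frames.shape[0] * self.frame_interval < self.cycle_length:
            raise ValueError("recording must cover at least one full cycle")
        if self.stimulus_times.size and np.any(np.diff(self.stimulus_times) <= 0):
            raise ValueError("stimulus times must be strictly increasing")

    @property
    def duration_ms(self) -> float:
        return self.frames.shape[0] * self.frame_interval


@dataclass
class ActivationMap:
    """Per-pixel activation time (ms, relative to the beat stimulus)."""

    times: np.ndarray
    valid: np.ndarray
    frame_interval: float
    pixel_size: float


@dataclass
class APDMap:
    """Per-pixel APD80 in ms."""

    apd80: np.ndarray
    valid: np.ndarray


@dataclass
class CVField:
    """Per-pixel conduction speed (cm/s) and unit propagation direction."""

    speed: np.ndarray
    direction: np.ndarray  # (H, W, 2) unit vectors, NaN where invalid
    valid: np.ndarray


@dataclass
class ROISet:
    """Disjoint HM / HT pixel masks used for regional summaries."""

    hm: np.ndarray
    ht: np.ndarray

    def __post_init__(self):
        self.hm = np.asarray(self.hm, dtype=bool)
        self.ht = np.asarray(self.ht, dtype=bool)
        if self.hm.shape != self.ht.shape:
            raise ValueError("ROI masks must share a shape")
        if np.any(self.hm & self.ht):
            raise ValueError("HM and HT ROIs must be disjoint")


def segment_beats(rec: OpticalRecording, *, average_last: int | None = None):
    """Cut the movie into per-stimulus windows of one cycle length.

    Returns ``(beat, n_used)`` where ``beat`` is a (F, H, W) array: the mean
    of the last ``average_last`` complete windows (all complete windows when
    ``None``).  Windows extending past the end of the record are dropped
    with a warning.
    """
    n_per = int(round(rec.cycle_length / rec.frame_interval))
    if n_per < 2:
        raise ValueError("cycle length must span at least two frames")
    starts = np.rint(rec.stimulus_times / rec.frame_interval).astype(int)
    windows = [s for s in starts if s >= 0 and s + n_per <= rec.frames.shape[0]]
    if len(windows) < len(starts):
        warnings.warn(
            f"dropping {len(starts) - len(windows)} incomplete beat window(s)",
            stacklevel=2,
        )
    if not windows:
        raise ValueError("no complete beat window in the recording")
    if average_last is not None:
        windows = windows[-average_last:]
    stack = np.stack(
        [rec.frames[s : s + n_per].astype(float) for s in windows], axis=0
    )
    return stack.mean(axis=0), len(windows)


def preprocess(
    beat: np.ndarray,
    *,
    spatial_sigma_px: float = 0.0,
    temporal_window_frames: int = 1,
    min_amplitude_frac: float = 0.05,
):
    """Condition a beat-averaged movie for map extraction.

    Polarity is detected globally (voltage dyes report depolarization as a
    *negative* fluorescence deflection) and corrected so the upstroke is
    positive-going; optional spatial Gaussian and temporal moving-average
    smoothing are applied; each pixel is normalized to [0, 1].  Pixels whose
    amplitude falls below ``min_amplitude_frac`` of the median amplitude are
    invalidated.

    Returns ``(normalized (F, H, W), valid (H, W))``.
    """
    x = np.asarray(beat, dtype=float)
    med = np.median(x, axis=0)
    up = (x.max(axis=0) - med).mean()
    down = (med - x.min(axis=0)).mean()
    if down > up:  # negative-going dye signal
        x = -x

    if spatial_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        x = gaussian_filter(x, sigma=(0.0, spatial_sigma_px, spatial_sigma_px))
    if temporal_window_frames > 1:
        from scipy.ndimage import uniform_filter1d

        x = uniform_filter1d(x, size=temporal_window_frames, axis=0, mode="nearest")

    lo = x.min(axis=0)
    amp = x.max(axis=0) - lo
    scale = np.median(amp)
    valid = amp > max(min_amplitude_frac * scale, 1e-12)
    safe = np.where(valid, amp, 1.0)
    norm = (x - lo) / safe
    norm[:, ~valid] = np.nan
    return norm, valid


def detect_activation(norm: np.ndarray, valid: np.ndarray, frame_interval: float,
                      pixel_size: float) -> ActivationMap:
    """Activation = time of maximal positive dF/dt, sub-frame interpolated.

    The discrete forward-difference maximum is refined by fitting a parabola
    through the three derivative samples around it; ties take the earlier
    frame.  A derivative maximum at the window edge invalidates the pixel.
    """
    d = np.diff(norm, axis=0)  # derivative sample k sits at (k + 0.5) dt
    nd = d.shape[0]
    dflat = np.where(np.isfinite(d), d, -np.inf)
    k = np.argmax(dflat, axis=0)  # argmax returns the first (earliest) max
    ok = valid & (k > 0) & (k < nd - 1)

    t = np.full(norm.shape[1:], np.nan)
    ii, jj = np.nonzero(ok)
    if ii.size:
        km = k[ii, jj]
        y0 = d[km - 1, ii, jj]
        y1 = d[km, ii, jj]
        y2 = d[km + 1, ii, jj]
        denom = y0 - 2 * y1 + y2
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        t[ii, jj] = (km + 0.5 + delta) * frame_interval
    return ActivationMap(times=t, valid=ok & np.isfinite(t),
                         frame_interval=frame_interval, pixel_size=pixel_size)


def compute_apd80(norm: np.ndarray, act: ActivationMap) -> APDMap:
    """APD80 per pixel: first 20 %-amplitude crossing after the peak.

    The normalized trace lives in [0, 1]; repolarization to 80 % means
    crossing the 0.2 level.  The crossing time is linearly interpolated
    between frames and referenced to the activation time.  Pixels whose
    trace never recrosses 0.2 before the window end are invalidated.
    """
    nf = norm.shape[0]
    dt = act.frame_interval
    level = 0.2
    tr = np.where(np.isfinite(norm), norm, -np.inf)
    pk = np.argmax(tr, axis=0)  # beat peak per pixel
    frame_idx = np.arange(nf)[:, None, None]
    below = (tr <= level) & (frame_idx > pk[None])
    has_cross = below.any(axis=0)
    kk = np.argmax(below, axis=0)  # first post-peak frame at/below the level
    ok = act.valid & has_cross & (kk >= 1)

    apd = np.full(norm.shape[1:], np.nan)
    ii, jj = np.nonzero(ok)
    if ii.size:
        k = kk[ii, jj]
        y0 = norm[k - 1, ii, jj]
        y1 = norm[k, ii, jj]
        frac = np.where(y0 == y1, 0.0, (y0 - level) / np.where(y0 == y1, 1.0, y0 - y1))
        t_cross = (k - 1 + frac) * dt
        val = t_cross - act.times[ii, jj]
        good = val > 0
        apd[ii[good], jj[good]] = val[good]
        ok[ii[~good], jj[~good]] = False
    return APDMap(apd80=apd, valid=ok)


def build_isochrones(act: ActivationMap, step_ms: float):
    """Level sets of activation time every ``step_ms`` (for display/QC).

    Returns a list of ``(level_ms, [contour arrays in pixel coords])``.
    """
    from skimage import measure

    t = np.where(act.valid, act.times, np.nan)
    finite = t[np.isfinite(t)]
    if finite.size < 2 or np.ptp(finite) == 0:
        return []
    levels = np.arange(
        np.ceil(finite.min() / step_ms) * step_ms, finite.max(), step_ms
    )
    filled = np.where(np.isfinite(t), t, finite.max() + 10 * step_ms)
    return [(float(lv), measure.find_contours(filled, lv)) for lv in levels]


def estimate_cv(
    act: ActivationMap,
    *,
    window: int = 5,
    min_neighbors: int = 6,
    speed_cap_cm_s: float = SPEED_CAP_CM_S,
) -> CVField:
    """Conduction velocity from local plane fits to the activation map.

    For each pixel a plane ``T(x, y) = a x + b y + c`` (x, y in mm) is fit
    by least squares over the valid pixels of a ``window x window``
    neighborhood.  The gradient ``g = (a, b)`` (ms/mm) is normal to the
    local isochrone; the velocity vector is ``g / |g|^2`` so the speed is
    ``1/|g|`` (mm/ms, reported as cm/s) and the direction is the unit
    isochrone normal.  Pixels with fewer than ``min_neighbors`` valid
    neighbors, a degenerate fit, or speed above the cap are invalidated.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    h, w = act.times.shape
    r = window // 2
    px = act.pixel_size
    t = np.where(act.valid, act.times, np.nan)

    speed = np.full((h, w), np.nan)
    direction = np.full((h, w, 2), np.nan)
    valid = np.zeros((h, w), dtype=bool)

    # fast path: pixels whose whole window is valid admit a separable
    # normal-equation solution (centered x/y offsets are orthogonal there)
    from scipy.ndimage import correlate

    off = np.arange(-r, r + 1, dtype=float) * px
    kx = np.tile(off, (window, 1))
    ky = kx.T
    t0 = np.where(act.valid, act.times, 0.0)
    n_valid = correlate(act.valid.astype(float), np.ones((window, window)),
                        mode="constant")
    full = act.valid & (np.rint(n_valid).astype(int) == window * window)
    sxx = float((kx**2).sum())
    gx_full = correlate(t0, kx, mode="constant") / sxx
    gy_full = correlate(t0, ky, mode="constant") / sxx
    fi, fj = np.nonzero(full)
    if fi.size:
        gxv, gyv = gx_full[fi, fj], gy_full[fi, fj]
        gn = np.hypot(gxv, gyv)
        with np.errstate(divide="ignore"):
            sp = 100.0 / gn
        good = (gn >= 1e-9) & (sp <= speed_cap_cm_s)
        speed[fi[good], fj[good]] = sp[good]
        direction[fi[good], fj[good], 0] = gxv[good] / gn[good]
        direction[fi[good], fj[good], 1] = gyv[good] / gn[good]
        valid[fi[good], fj[good]] = True

    for i in range(h):
        i0, i1 = max(0, i - r), min(h, i + r + 1)
        for j in range(w):
            if not act.valid[i, j] or full[i, j]:
                continue
            j0, j1 = max(0, j - r), min(w, j + r + 1)
            patch = t[i0:i1, j0:j1]
            m = np.isfinite(patch)
            n = int(m.sum())
            if n < min_neighbors:
                continue
            yy, xx = np.nonzero(m)
            X = np.column_stack(
                [
                    (xx + j0 - j) * px,
                    (yy + i0 - i) * px,
                    np.ones(n),
                ]
            )
            coef, *_ = np.linalg.lstsq(X, patch[m], rcond=None)
            gx, gy = coef[0], coef[1]
            gnorm = np.hypot(gx, gy)
            if gnorm < 1e-9:
                continue
            s = 100.0 / gnorm  # 1/|g| mm/ms -> cm/s
            if s > speed_cap_cm_s or s <= 0:
                continue
            speed[i, j] = s
            direction[i, j] = (gx / gnorm, gy / gnorm)
            valid[i, j] = True
    return CVField(speed=speed, direction=direction, valid=valid)


def regional_relative_difference(values: np.ndarray, valid: np.ndarray,
                                 rois: ROISet, *, summary: str = "median",
                                 min_pixels: int = 10) -> float:
    """HT-vs-HM regional dispersion: 100*(HT - HM)/HM of regional summaries.

    ``values`` is a per-pixel map (APD80 in ms or speed in cm/s);
    ``summary`` is ``"median"`` (default) or ``"mean"``.
    """
    stat = {"median": np.median, "mean": np.mean}[summary]
    out = {}
    for name, mask in (("hm", rois.hm), ("ht", rois.ht)):
        sel = mask & valid & np.isfinite(values)
        if int(sel.sum()) < min_pixels:
            raise ValueError(f"{name.upper()} ROI has fewer than {min_pixels} valid pixels")
        out[name] = float(stat(values[sel]))
    if out["hm"] == 0:
        raise ValueError("HM regional summary is zero; relative difference undefined")
    return 100.0 * (out["ht"] - out["hm"]) / out["hm"]


def analyze_recording(
    rec: OpticalRecording,
    rois: ROISet | None = None,
    *,
    average_last: int | None = 3,
    spatial_sigma_px: float = 1.0,
    temporal_window_frames: int = 3,
    cv_window: int = 5,
    summary: str = "median",
):
    """Full movie-to-maps pipeline.

    Averages the last beats of the drive train, preprocesses, and extracts
    activation, APD80 and CV maps.  When ``rois`` is given the regional
    relative differences (HT-HM)/HM are included.

    Returns a dict with keys ``activation``, ``apd``, ``cv`` and, with ROIs,
    ``delta_cv_pct`` / ``delta_apd_pct``.
    """
    beat, _ = segment_beats(rec, average_last=average_last)
    norm, valid = preprocess(
        beat,
        spatial_sigma_px=spatial_sigma_px,
        temporal_window_frames=temporal_window_frames,
    )
    act = detect_activation(norm, valid, rec.frame_interval, rec.pixel_size)
    apd = compute_apd80(norm, act)
    cv = estimate_cv(act, window=cv_window)
    out = {"activation": act, "apd": apd, "cv": cv}
    if rois is not None:
        out["delta_cv_pct"] = regional_relative_difference(
            cv.speed, cv.valid, rois, summary=summary
        )
        out["delta_apd_pct"] = regional_relative_difference(
            apd.apd80, apd.valid, rois, summary=summary
        )
    return out
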