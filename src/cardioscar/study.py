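"""End-to-end synthetic two-arm study.

Reproduces the analysis structure of a randomized, placebo-controlled
post-infarction cell-therapy experiment on fully synthetic data: per animal,
two LGE phantoms (baseline / follow-up) implementing the arm's scar
remodeling rule, one optical-mapping movie with arm-specific HT/HM
electrophysiology, and a histology score table; every stream is pushed
through the corresponding analysis module and the arm contrast is tested
per endpoint with the exact Mann-Whitney test.

Remodeling rules (angular scar sectors on the phantom wall):

* **control** — a fraction of the epicardial heterogeneous-tissue (HT)
  sector converts to dense scar (DS) between timepoints while the HT band
  keeps its width (HT is replenished from healthy myocardium): DS grows,
  HT is stable.
* **treated** — the HT sector widens while DS stays put: HT grows, DS is
  stable.

Endocardial scar grows identically in both arms.  Analysis stages never see
the arm label; it is attached only when the per-animal endpoint values
reach the statistics stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cmr as cmr_mod
from .histology import HISTO_VARIABLES, animal_summary
from .optical import analyze_recording
from .stats import exact_mann_whitney, median_iqr
from .synth.cmr import ScarRegion, SyntheticCMRSpec, generate_cmr
from .synth.histology import SyntheticHistoSpec, generate_histology
from .synth.optical import APTemplate, SyntheticOpticalSpec, disk_mask, generate_optical

__all__ = ["ArmParams", "CMRParams", "OpticalParams", "StudyConfig", "StudyReport", "run_study"]


# epicardial histology score distributions (levels 1..5) per arm; the
# treated border zone has less fibrosis, better viability/vascularization
# and more, better-polarized connexin 43
TREATED_EPI_PROBS = {
    "fibrosis": (0.5, 0.4, 0.1, 0.0, 0.0),
    "cx43_quantity": (0.0, 0.0, 0.1, 0.6, 0.3),
    "cx43_polarity": (0.1, 0.3, 0.5, 0.1, 0.0),
    "viability": (0.0, 0.0, 0.3, 0.6, 0.1),
    "vascularization": (0.0, 0.1, 0.7, 0.2, 0.0),
}
CONTROL_EPI_PROBS = {
    "fibrosis": (0.1, 0.4, 0.4, 0.1, 0.0),
    "cx43_quantity": (0.0, 0.1, 0.5, 0.4, 0.0),
    "cx43_polarity": (0.4, 0.5, 0.1, 0.0, 0.0),
    "viability": (0.0, 0.2, 0.6, 0.2, 0.0),
    "vascularization": (0.05, 0.35, 0.55, 0.05, 0.0),
}
# endocardial border zone is unaffected by the therapy in either arm
ENDO_PROBS = {var: (0.1, 0.3, 0.4, 0.2, 0.0) for var in HISTO_VARIABLES}


@dataclass
class ArmParams:
    """Arm-specific remodeling and electrophysiology parameters."""

    name: str
    #: fraction of the baseline epicardial HT sector converted to DS
    epi_ht_to_ds_conversion: float
    #: relative growth of the epicardial HT sector width
    epi_ht_growth: float
    #: HT conduction velocity as a fraction of HM velocity
    ht_cv_ratio: float
    #: HT APD80 as a multiple of HM APD80
    ht_apd_ratio: float
    epi_histology_probs: dict = field(default_factory=dict)

    def validate(self):
        if not (0.0 <= self.epi_ht_to_ds_conversion <= 1.0):
            raise ValueError("conversion fraction must be in [0, 1]")
        if self.epi_ht_growth < 0:
            raise ValueError("HT growth fraction must be >= 0")
        if self.ht_cv_ratio <= 0 or self.ht_apd_ratio <= 0:
            raise ValueError("electrophysiology ratios must be > 0")


@dataclass
class CMRParams:
    grid_shape: tuple[int, int, int] = (40, 40, 6)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 5.0)
    remote_mean: float = 100.0
    remote_sd: float = 10.0
    noise_sd: float = 2.0
    n_theta: int = 48


@dataclass
class OpticalParams:
    grid_shape: tuple[int, int] = (32, 32)
    pixel_size: float = 1.0
    frame_interval: float = 2.0
    n_beats: int = 3
    cycle_length: float = 600.0
    hm_velocity_cm_s: float = 50.0
    hm_apd80_ms: float = 200.0
    snr: float = 20.0
    roi_margin_px: int = 3


@dataclass
class StudyConfig:
    """Two-arm study configuration.

    Defaults mirror the reference design: 10 treated vs 9 control animals;
    the control arm converts 80 % of the epicardial HT band to DS while the
    treated arm grows HT by 50 % with stable DS; HT electrophysiology is
    markedly depressed in controls (CV ratio ~0.52, APD ratio 1.40) and
    mildly in the treated arm (0.80 / 1.12).
    """

    n_treated: int = 10
    n_control: int = 9
    treated: ArmParams = field(
        default_factory=lambda: ArmParams(
            "treated", 0.0, 0.5, 0.80, 1.12, dict(TREATED_EPI_PROBS)
        )
    )
    control: ArmParams = field(
        default_factory=lambda: ArmParams(
            "control", 0.8, 0.0, 0.517, 1.40, dict(CONTROL_EPI_PROBS)
        )
    )
    #: relative growth of both endocardial scar sectors (both arms alike)
    endo_growth: float = 0.45
    cmr: CMRParams = field(default_factory=CMRParams)
    optical: OpticalParams = field(default_factory=OpticalParams)
    histo_sections: int = 5
    #: SD of the multiplicative per-animal jitter applied to sector widths,
    #: growth/conversion fractions and electrophysiology ratios
    jitter: float = 0.06

    def validate(self):
        if self.n_treated < 3 or self.n_control < 3:
            raise ValueError("need at least 3 animals per arm")
        self.treated.validate()
        self.control.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        cfg = cls()
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown study option: {key}")
            cur = getattr(cfg, key)
            if dataclasses.is_dataclass(cur) and isinstance(val, dict):
                setattr(cfg, key, dataclasses.replace(cur, **val))
            else:
                setattr(cfg, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


CMR_ENDPOINTS = ("dEnDS_pct", "dEnHT_pct", "dEpDS_pct", "dEpHT_pct")
OPTICAL_ENDPOINTS = ("delta_cv_pct", "delta_apd_pct")


@dataclass
class StudyReport:
    """Per-animal endpoint values plus arm-contrast statistics."""

    per_animal: pd.DataFrame
    endpoints: pd.DataFrame
    baseline: pd.DataFrame
    config: StudyConfig
    seed: int

    def endpoint(self, name: str) -> pd.Series:
        return self.endpoints.set_index("endpoint").loc[name]


def _jittered(rng, value, sd_frac, lo=None, hi=None):
    out = value * (1.0 + sd_frac * rng.standard_normal())
    if lo is not None:
        out = max(out, lo)
    if hi is not None:
        out = min(out, hi)
    return out


def _animal_cmr_specs(cfg: StudyConfig, arm: ArmParams, rng) -> tuple[SyntheticCMRSpec, SyntheticCMRSpec, dict]:
    """Baseline and follow-up phantom specs implementing the arm's rule."""
    j = cfg.jitter
    endo_r = _jittered(rng, 14.0, 0.05, lo=10.0)
    wall = _jittered(rng, 8.0, 0.05, lo=5.0)
    geom = (endo_r, endo_r + wall)

    ep_ds = _jittered(rng, 110.0, j, lo=40.0)
    ep_ht = _jittered(rng, 70.0, j, lo=20.0)
    en_ds = _jittered(rng, 150.0, j, lo=40.0)
    en_ht = _jittered(rng, 40.0, j, lo=15.0)
    ds_off = _jittered(rng, 3.6, 0.02, lo=3.2)
    ht_off = _jittered(rng, 2.5, 0.02, lo=2.2, hi=2.9)
    ns = cfg.cmr.grid_shape[2]

    def regions(ep_ds_w, ep_ht_w, en_ds_w, en_ht_w):
        return [
            ScarRegion(0.0, ep_ds_w, 0, ns, "epi", ds_off),
            ScarRegion(ep_ds_w, ep_ds_w + ep_ht_w, 0, ns, "epi", ht_off),
            ScarRegion(0.0, en_ds_w, 0, ns, "endo", ds_off),
            ScarRegion(en_ds_w, en_ds_w + en_ht_w, 0, ns, "endo", ht_off),
        ]

    conv = _jittered(rng, arm.epi_ht_to_ds_conversion, 0.0, lo=0.0, hi=1.0)
    conv = min(max(conv + 0.08 * rng.standard_normal(), 0.0), 1.0)
    growth = max(arm.epi_ht_growth + 0.08 * rng.standard_normal(), 0.0)
    endo_g = max(cfg.endo_growth + 0.10 * rng.standard_normal(), 0.0)
    stable = lambda w: w * (1.0 + 0.03 * rng.standard_normal())  # noqa: E731

    ep_ds2 = stable(ep_ds) + conv * ep_ht
    ep_ht2 = stable(ep_ht) * (1.0 + growth)
    en_ds2 = stable(en_ds) * (1.0 + endo_g)
    en_ht2 = stable(en_ht) * (1.0 + endo_g)
    # keep sector sums within the circle, leaving room for the remote ROI
    scale_ep = min(1.0, 300.0 / (ep_ds2 + ep_ht2))
    scale_en = min(1.0, 300.0 / (en_ds2 + en_ht2))

    common = dict(
        grid_shape=cfg.cmr.grid_shape,
        voxel_size=cfg.cmr.voxel_size,
        wall_geometry=geom,
        remote_mean=cfg.cmr.remote_mean,
        remote_sd=cfg.cmr.remote_sd,
        noise_sd=cfg.cmr.noise_sd,
    )
    seed1, seed2 = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    spec1 = SyntheticCMRSpec(
        scar_regions=regions(ep_ds, ep_ht, en_ds, en_ht), seed=seed1, **common
    )
    spec2 = SyntheticCMRSpec(
        scar_regions=regions(
            ep_ds2 * scale_ep, ep_ht2 * scale_ep, en_ds2 * scale_en, en_ht2 * scale_en
        ),
        seed=seed2,
        **common,
    )
    cine = {
        "ed_scale": 1.0,
        "es_scale": float(np.sqrt(1.0 - _jittered(rng, 0.30, 0.10, lo=0.1, hi=0.6))),
        "fu_dilation": _jittered(rng, 1.25, 0.04, lo=1.0),
        "geom": geom,
    }
    return spec1, spec2, cine


def _cine_contours(cfg: StudyConfig, geom, endo_scale: float) -> cmr_mod.WallContours:
    from .synth.cmr import _circle

    nx, ny, ns = cfg.cmr.grid_shape
    dx, dy, _ = cfg.cmr.voxel_size
    center = (0.5 * nx * dx, 0.5 * ny * dy)
    endo_r, epi_r = geom
    return cmr_mod.WallContours(
        {
            s: {
                "endo": _circle(center, endo_r * endo_scale, 72),
                "epi": _circle(center, max(epi_r, endo_r * endo_scale + 1.0), 72),
            }
            for s in range(ns)
        }
    )


def _quantify_phantom(cfg: StudyConfig, result, ed_contours, es_contours) -> cmr_mod.ScarQuantification:
    """The blinded analysis chain for one phantom."""
    volume, contours = result.volume, result.contours
    # identical to split_wall_halves(contours, volume): the generator derives
    # its masks from the same contours with the same rule
    masks = result.masks
    z = cmr_mod.normalize_to_sd_units(volume, result.remote_roi, masks)
    surf_en = cmr_mod.build_wall_surface(contours, volume, "endo", n_theta=cfg.cmr.n_theta)
    surf_ep = cmr_mod.build_wall_surface(contours, volume, "epi", n_theta=cfg.cmr.n_theta)
    map_en = cmr_mod.project_half_wall_si(z, masks.endo_half, surf_en)
    map_ep = cmr_mod.project_half_wall_si(z, masks.epi_half, surf_ep)
    return cmr_mod.quantify(
        map_en,
        map_ep,
        z,
        ed_contours=ed_contours,
        es_contours=es_contours,
        lge_volume=volume,
    )


def _animal_optical_spec(cfg: StudyConfig, arm: ArmParams, rng) -> SyntheticOpticalSpec:
    o = cfg.optical
    h, w = o.grid_shape
    radius = 0.22 * min(h, w)
    center = (0.5 * (h - 1), 0.62 * (w - 1))
    mask = disk_mask((h, w), center, radius)
    amplitude = 1000.0
    cv_ratio = _jittered(rng, arm.ht_cv_ratio, cfg.jitter, lo=0.15, hi=0.95)
    apd_ratio = _jittered(rng, arm.ht_apd_ratio, 0.04, lo=1.01)
    return SyntheticOpticalSpec(
        grid_shape=o.grid_shape,
        pixel_size=o.pixel_size,
        frame_interval=o.frame_interval,
        n_beats=o.n_beats,
        cycle_length=o.cycle_length,
        ap_template=APTemplate(amplitude=amplitude, apd80_ms=_jittered(rng, o.hm_apd80_ms, 0.03)),
        hm_velocity_cm_s=_jittered(rng, o.hm_velocity_cm_s, 0.04, lo=20.0),
        ht_mask=mask,
        ht_velocity_ratio=cv_ratio,
        ht_apd_ratio=apd_ratio,
        noise_sd=amplitude / o.snr,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _animal_histo_spec(cfg: StudyConfig, arm: ArmParams, animal_id: str, rng) -> SyntheticHistoSpec:
    probs = {
        "endo": dict(ENDO_PROBS),
        "epi": dict(arm.epi_histology_probs or ENDO_PROBS),
    }
    return SyntheticHistoSpec(
        animal_ids=(animal_id,),
        n_sections=cfg.histo_sections,
        level_probs=probs,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def run_study(config: StudyConfig | None = None, *, seed: int = 0) -> StudyReport:
    """Simulate and analyze one full two-arm study.

    Per animal: generate baseline and follow-up LGE phantoms under the
    arm's remodeling rule, one optical recording, and a histology table;
    run every analysis module; then compare arms endpoint-by-endpoint with
    the exact Mann-Whitney test.  Deterministic for a given config + seed.
    """
    cfg = config or StudyConfig()
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    arms = [("treated", cfg.treated)] * cfg.n_treated + [
        ("control", cfg.control)
    ] * cfg.n_control
    child_seeds = ss.spawn(len(arms))

    animal_rows = []
    baseline_rows = []
    for idx, ((arm_name, arm), child) in enumerate(zip(arms, child_seeds)):
        rng = np.random.default_rng(child)
        animal_id = f"{arm_name[:1].upper()}{idx:02d}"

        spec1, spec2, cine = _animal_cmr_specs(cfg, arm, rng)
        res1, res2 = generate_cmr(spec1), generate_cmr(spec2)
        ed1 = _cine_contours(cfg, cine["geom"], cine["ed_scale"])
        es1 = _cine_contours(cfg, cine["geom"], cine["ed_scale"] * cine["es_scale"])
        ed2 = _cine_contours(cfg, cine["geom"], cine["fu_dilation"])
        es2 = _cine_contours(cfg, cine["geom"], cine["fu_dilation"] * cine["es_scale"])
        q1 = _quantify_phantom(cfg, res1, ed1, es1)
        q2 = _quantify_phantom(cfg, res2, ed2, es2)

        opt_spec = _animal_optical_spec(cfg, arm, rng)
        opt = generate_optical(opt_spec)
        optical_out = analyze_recording(
            opt.recording, rois=opt.truth.rois(cfg.optical.roi_margin_px)
        )

        histo = generate_histology(_animal_histo_spec(cfg, arm, animal_id, rng))
        means = animal_summary(histo.sections).set_index(["compartment", "variable"])

        row = {
            "animal_id": animal_id,
            "arm": arm_name,
            "dEnDS_pct": cmr_mod.percent_change(q1.EnDS, q2.EnDS),
            "dEnHT_pct": cmr_mod.percent_change(q1.EnHT, q2.EnHT),
            "dEpDS_pct": cmr_mod.percent_change(q1.EpDS, q2.EpDS),
            "dEpHT_pct": cmr_mod.percent_change(q1.EpHT, q2.EpHT),
            "delta_cv_pct": optical_out["delta_cv_pct"],
            "delta_apd_pct": optical_out["delta_apd_pct"],
        }
        for comp in ("endo", "epi"):
            for var in HISTO_VARIABLES:
                row[f"histo_{comp}_{var}"] = float(
                    means.loc[(comp, var), "weighted_mean_percent"]
                )
        animal_rows.append(row)
        baseline_rows.append(
            {"animal_id": animal_id, "arm": arm_name, **q1.to_dict()}
        )

    per_animal = pd.DataFrame(animal_rows)
    baseline = pd.DataFrame(baseline_rows)

    endpoint_names = list(CMR_ENDPOINTS) + list(OPTICAL_ENDPOINTS) + [
        f"histo_{comp}_{var}" for comp in ("endo", "epi") for var in HISTO_VARIABLES
    ]
    ep_rows = []
    for name in endpoint_names:
        tv = per_animal.loc[per_animal.arm == "treated", name].to_numpy()
        cv = per_animal.loc[per_animal.arm == "control", name].to_numpy()
        res = exact_mann_whitney(tv, cv)
        tm, tq1, tq3 = median_iqr(tv)
        cm, cq1, cq3 = median_iqr(cv)
        ep_rows.append(
            {
                "endpoint": name,
                "treated_median": tm,
                "treated_q1": tq1,
                "treated_q3": tq3,
                "control_median": cm,
                "control_q1": cq1,
                "control_q3": cq3,
                "U": res.statistic,
                "p_value": res.p_two_sided,
                "method": res.method,
            }
        )
    endpoints = pd.DataFrame(ep_rows)
    return StudyReport(
        per_animal=per_animal,
        endpoints=endpoints,
        baseline=baseline,
        config=cfg,
        seed=seed,
    )
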