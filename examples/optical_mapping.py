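"""Activation, APD80 and conduction velocity from a synthetic dye movie.

A paced wavefront crosses a 64x64 grid containing a slow, long-APD
heterogeneous-tissue (HT) disk; the analysis recovers the regional
electrophysiology and the HT-vs-HM dispersion (HT-HM)/HM.
"""

import numpy as np

from cardioscar.optical import analyze_recording
from cardioscar.synth.optical import (
    SyntheticOpticalSpec,
    disk_mask,
    generate_optical,
)

spec = SyntheticOpticalSpec(
    grid_shape=(64, 64),
    pixel_size=0.5,  # mm
    frame_interval=1.0,  # ms (1 kHz)
    n_beats=3,
    hm_velocity_cm_s=50.0,
    ht_mask=disk_mask((64, 64), (31.5, 40.0), 13.0),
    ht_velocity_ratio=0.55,  # HT conducts at 55 % of HM speed
    ht_apd_ratio=1.3,  # HT APD80 is 30 % longer
    noise_sd=100.0,  # SNR 10 vs the 1000-count AP amplitude
    seed=7,
)
res = generate_optical(spec)
rois = res.truth.rois(margin_px=3)
out = analyze_recording(res.recording, rois=rois)

cv, apd = out["cv"], out["apd"]
hm_cv = np.median(cv.speed[rois.hm & cv.valid])
ht_cv = np.median(cv.speed[rois.ht & cv.valid])
hm_apd = np.median(apd.apd80[rois.hm & apd.valid])
ht_apd = np.median(apd.apd80[rois.ht & apd.valid])

print(f"HM conduction velocity: {hm_cv:.1f} cm/s (true 50.0)")
print(f"HT conduction velocity: {ht_cv:.1f} cm/s (true 27.5)")
print(f"HM APD80: {hm_apd:.1f} ms (true 200);  HT APD80: {ht_apd:.1f} ms (true 260)")
print(f"Delta CV  (HT-HM)/HM = {out['delta_cv_pct']:+.1f} %")
print(f"Delta APD (HT-HM)/HM = {out['delta_apd_pct']:+.1f} %")
print("Negative Delta CV / positive Delta APD quantify the electrical")
print("heterogeneity of the scar border zone relative to healthy muscle.")
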