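"""Render one gated/ungated phantom pair and quantify SNR/CNR.

Builds the default vessel scene, renders a gated and an ungated T1W
acquisition with matched noise-only images, and quantifies both with
ground-truth ROIs.
"""

from vesselrep import (
    CardiacModel,
    T1W_GATED,
    T1W_UNGATED,
    default_scene,
    quantify,
    render_scene,
)
from vesselrep.cohort import CohortRecord
from vesselrep.pipeline import build_synthetic_rois

cardiac = CardiacModel(mean_rr_ms=1000.0, sd_rr_ms=50.0)
for protocol in (T1W_GATED, T1W_UNGATED):
    scene = default_scene(protocol, "T1W")
    acq = render_scene(scene, protocol, cardiac, repeat_index=1, seed=42)
    rois = build_synthetic_rois(CohortRecord(1, "T1W", protocol.name.split("-")[1], 1, acq, scene))
    m = quantify(acq, rois)
    print(f"{protocol.name}: sigma={m.sigma:.4f}  SNR wall={m.snr_wall:.1f} "
          f"muscle={m.snr_muscle:.1f} lumen={m.snr_lumen:.1f}  "
          f"CNR={m.cnr_wall:.1f}  CNR_eff={m.cnr_eff:.1f} (T_slice={m.t_slice_min:.2f} min)")

print()
print("sigma is the noise-only ROI SD (~0.695 x per-channel sigma of 0.1);")
print("SNR = SI/sigma x 0.695 restores the per-channel scale, so the wall sits")
print("near its calibrated SNR of ~10 and the suppressed lumen near ~3.")
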