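"""Simulate one patient side and measure it with the full pipeline.

Builds a synthetic mandible-angle scene (cortical-shelled slab, onlay
graft block, titanium screw), programs 50% graft resorption between the
two scans, misaligns and corrupts them like real CBCT acquisitions, then
runs registration -> normalization -> threshold level-set segmentation ->
largest-component volumetry.  The measured percent change should land
within a few points of the programmed -50%.
"""

from graftquant.phantom import PhantomSpec, generate_pair
from graftquant.pipeline import run_side

spec = PhantomSpec(seed=1, followup_volume_fraction=0.5)
baseline, followup, roi, truth = generate_pair(spec)

print(
    f"ground truth: baseline {truth.graft_volume_baseline:.1f} mm^3, "
    f"6 months {truth.graft_volume_followup:.1f} mm^3 "
    f"({truth.percent_change:+.1f}%)"
)

report = run_side(baseline, followup, roi, transform="auto")
print(
    f"measured:     baseline {report.volume_baseline_mm3:.1f} mm^3, "
    f"6 months {report.volume_followup_mm3:.1f} mm^3 "
    f"({report.percent_change:+.1f}%)"
)
print(
    f"registration loss {report.registration['loss']:.3g} "
    f"(vs {report.registration['init_loss']:.3g} before alignment); "
    f"segmentation converged in {report.segmentation['baseline']['iterations']} / "
    f"{report.segmentation['followup']['iterations']} iterations"
)
print("Absolute volumes read systematically low (the threshold contour sits")
print("inside the blurred surface, and the mask margins shave the attachment")
print("face), but the bias is proportional at both timepoints, so the percent")
print("change - the trial's endpoint - is recovered within a few points.")
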