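"""Render a synthetic Graf standard-plane hip phantom frame.

Builds a scene with a known true alpha-angle of 70 degrees, renders it
once clean and once with moderate speckle/blur, and reports where the
ground-truth landmarks sit. The printed pixel coordinates are (row, col)
with the origin at the top-left; the rim is the corner where the bony
roof leaves the near-vertical iliac margin.
"""

from grafangle import NOISELESS, NoiseConfig, make_scene, render_frame

scene = make_scene(alpha_deg=70.0, inclination_deg=2.0)
print(f"true alpha          : {scene.alpha_true:.1f} deg")
print(f"true iliac tilt     : {scene.inclination_true:.1f} deg")
print(f"acetabular rim      : {tuple(round(float(v), 1) for v in scene.rim_point)}")
print(f"lower limb of ilium : {tuple(round(float(v), 1) for v in scene.ilium_lower_limb_point)}")

clean, gt = render_frame(scene, NOISELESS, seed=0)
noisy, _ = render_frame(scene, NoiseConfig(speckle_scale=0.2, blur_sigma_px=1.0), seed=0)
print(f"clean frame   : shape {clean.shape}, max intensity {clean.pixels.max()}")
print(f"noisy frame   : shape {noisy.shape}, max intensity {noisy.pixels.max()}")
print(f"ground truth  : diagnostic={gt.diagnostic_quality}, rim box {gt.rim_box}")
print("the rim box is the 24x24 px region a landmark detector should recover")
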