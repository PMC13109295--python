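"""Render visible and amodal per-leaf instance masks for a rosette.

Builds the 3D plant from the preset grammar, rasterizes it top-down with a
z-buffer, and reports per-leaf pixel areas and visibility (visible pixels /
amodal pixels — 1.0 means the leaf is entirely unoccluded).
"""

from leafgen import CameraSpec, expand_hierarchical, interpret, load_grammar, preset_path
from leafgen.render import crop_patches, render_masks

grammar = load_grammar(preset_path("rosette"))
string = expand_hierarchical(grammar, 10, seed=7)
model = interpret(string, angle=grammar.default_angle, step=grammar.default_step)
print(f"plant model: {model.leaf_count} leaves, {model.triangle_count()} triangles")

camera = CameraSpec.top_down(image_size=(256, 256), extent=6.0)
masks = render_masks(model, camera, mode="both")
print("leaf  visible_px  amodal_px  visibility")
for k in masks.instance_ids:
    vis = int(masks.visible_masks[k].sum())
    amo = int(masks.amodal_masks[k].sum())
    print(f"  {k:2d}  {vis:9d}  {amo:8d}  {masks.visibility[k]:.2f}")
print("visibility < 1 means that leaf is partly hidden behind nearer leaves.")

patches = crop_patches(masks, pad=2)
print(f"\n{len(patches)} mask patches cropped to padded tight boxes, e.g. "
      f"instance {patches[0].instance_id} -> bbox {patches[0].bbox}")
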