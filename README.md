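# leafgen

Structure-aware synthetic training data for leaf instance segmentation.

Plant phenotyping pipelines need per-leaf instance masks, but hand-annotating
overlapping leaves is slow and expensive. `leafgen` sidesteps annotation by
*generating* the data: procedural plant models built from L-systems come with
pixel-perfect per-leaf masks for free, and textured plant images are composed
on top of those masks. The package targets researchers building or evaluating
instance segmenters for rosette plants (Arabidopsis-like, top-down imagery)
and shoot-like plants, and anyone who needs occlusion-free (amodal) leaf
masks, which are nearly impossible to annotate by hand.

## What it computes

**Plant structure.** An L-system is a formal grammar G = {V, T, ω, P}:
starting from the axiom ω, production rules P rewrite all symbols in parallel
for *n* iterations. Rules may be parametric (`A(x) : x > 0 -> F(x) A(x-1)`)
and stochastic (weighted successor alternatives). Plants are modeled
*hierarchically*: a plant-level grammar G_p contains placeholder symbols bound
to a leaf-level grammar G_l, and every placeholder occurrence is replaced by a
freshly derived leaf string wrapped in organ-span markers — so the derived
string, and hence the 3D model M_p, decomposes into individual leaf parts
M_l^k for k = 1..K.

**Geometry and masks.** A 3D turtle (position plus orthonormal heading frame)
interprets the string through the classic bracketed-L-system command table
(`F` draw, `+ - & ^ \ /` rotations, `[ ]` branch push/pop, `{ . }` polygon
capture), emitting one triangle mesh per organ instance. A software z-buffer
rasterizes the model under an orthographic (top-down) or perspective camera
into an `InstanceMaskSet`: visible masks (occlusion-clipped; pairwise disjoint
and partitioning the leaf foreground), amodal masks (each leaf rendered alone,
occluders ignored), per-leaf visibility fractions, and tight COCO-style boxes.

**Images.** Each leaf mask is cropped to its padded bounding box, turned into
an RGB texture by a `TextureGenerator` (the built-in one is deterministic and
seedable: distance-transform rim shading, a principal-axis vein skeleton, and
speckle noise; a trained mask-to-image network plugs into the same interface),
and pasted back-to-front over a procedural soil background, replacing only
mask-foreground pixels. Self-supervised refinement data — pairs of
(leaf-replaced, original) real images built from a segmenter's extraction
archive — is constructed by the same composition operator, and the
adversarial/reconstruction objectives used to train such networks
(L_cGAN = E[log D] + E[log(1-D)], L_1, weighted 0.01 : 1) are provided as
pure array computations.

**Evaluation.** AP@50 / AP@75 (greedy score-ranked matching at IoU ≥ τ, both
a "percentage of correctly predicted instances" variant and 101-point COCO
AP) and foreground MAE (mean |difference| over ground-truth leaf pixels).

## Worked example

```python
from leafgen import (CameraSpec, expand_hierarchical, interpret,
                     load_grammar, preset_path)
from leafgen.render import render_masks

grammar = load_grammar(preset_path("rosette"))
string = expand_hierarchical(grammar, 10, seed=7)   # 8 leaf organ spans
model = interpret(string, angle=grammar.default_angle)
masks = render_masks(model, CameraSpec.top_down(image_size=(256, 256), extent=6.0))
for k in masks.instance_ids[:3]:
    print(k, int(masks.visible_masks[k].sum()), round(masks.visibility[k], 2))
```

prints

```
1 1299 0.78
2 1255 0.77
3 1201 0.76
```

— leaf 1 covers 1299 visible pixels and is 78 % visible (22 % of its amodal
extent is hidden behind nearer leaves). The scripts in `examples/` walk
through each capability: derivation, mask rendering, dataset generation with
COCO export, and evaluation; `examples/03_compose_dataset.py` ends with
`masks identical: True`, the lossless COCO round trip. A thin CLI mirrors the
library (`leafgen generate -c config.yaml`, `leafgen render-masks rosette`,
`leafgen eval --pred p.json --gt g.json`, `leafgen fixtures --preset shoot`).

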