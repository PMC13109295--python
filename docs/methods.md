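# Methods

## Model overview

`leafgen` treats synthetic-data generation for leaf instance segmentation as
four composable stages:

1. **Structure** — a hierarchical, stochastic, parametric L-system G = {V, T,
   ω, P} derives a symbol string; placeholder symbols bound to organ-level
   sub-grammars are expanded into marker-delimited organ spans, one per leaf
   (or branch) instance.
2. **Geometry** — a 3D turtle interprets the string into per-organ triangle
   meshes; the plant model is the labeled union of those meshes.
3. **Appearance** — a z-buffered rasterizer projects the model into per-leaf
   visible/amodal masks; mask patches become RGB textures; textures are
   composited over a background, back-to-front, masked to the leaf foreground.
4. **Measurement** — AP at an IoU threshold for instance segmentations and
   foreground MAE for image fidelity.

The package's assumption throughout is that *structure carries the
annotation*: because each mask is derived from a known organ mesh, labels are
exact by construction, and occlusion-free (amodal) masks cost nothing extra.

## Grammar semantics and numerical choices

- Rewriting is context-free and parallel (D0L / stochastic 0L). Symbols with
  no applicable rule are copied; among rules for a symbol, the first whose
  guard holds is applied; among its successors, one is sampled by normalized
  weight. Iteration 0 returns the axiom.
- Stochastic draws use a counter-based scheme: the uniform for position *p*
  at iteration *i* comes from a generator seeded by the tuple (seed, i, p).
  Adding rules for unrelated symbols therefore never perturbs choices
  elsewhere — grammar edits stay locally reproducible.
- Sub-grammar occurrence *k* derives with a child seed hashed from
  (seed, k), so organs are internally independent yet jointly reproducible.
- Rule parameters/conditions use a closed expression language (+, −, ×, ÷,
  unary −, comparisons, sin/cos/pow in degrees) compiled through a
  whitelisted AST; anything outside the whitelist is a parse error.
- Organ spans are emitted as paired marker symbols inside the string, so the
  turtle can assign geometry to instances in a single pass. Leaf instances
  are renumbered 1..K in order of appearance at interpretation time; branch
  organs get ids above K; bare stem geometry is instance 0.

## Turtle and rasterizer

- Coordinates are right-handed, +Z up; the turtle starts at the origin
  heading +Z (left +X, up +Y). A top-down orthographic camera on the −Z axis
  is the default because rosette datasets are photographed from above;
  perspective projection is available for shoots.
- Stems are ribbon quads of the current width (masks, not shading, are the
  product); leaves are polygon fans from the first captured vertex.
  Zero-area triangles are dropped at emission.
- Rotations are Rodrigues rotations about the turtle's own axes with
  Gram–Schmidt re-orthonormalization each step; the frame stays orthonormal
  to < 1e-8 over 10⁴ random rotations (tested).
- Rasterization: per-triangle barycentric coverage at pixel centers
  ((col + 0.5, row + 0.5)), per-pixel z-buffer over *all* organs; stem/branch
  geometry occludes but labels 0. Depth ties between exactly coplanar leaves
  go to the lower instance id (organs are processed in ascending id with a
  strict depth test), making renders deterministic. Masks are hard binary —
  no anti-aliasing — because annotations must be exact labels.
- Instances with fewer than 16 visible pixels (configurable `min_area`) are
  skipped at patch-cropping time: sub-pixel slivers of almost fully occluded
  leaves destabilize both texturing and AP evaluation.

## Texture and composition

- The default texture generator is deliberately procedural and deterministic:
  base color jittered per instance, shaded by the normalized Euclidean
  distance transform (rim darkening in [0,1]), a midrib along the mask's
  principal axis with Poisson-sampled secondary veins, and seeded Gaussian
  speckle. It exists so the entire pipeline runs and is testable with no
  trained network; a learned mask-to-image model drops into the same
  one-method interface (`generate(mask) -> texture`), with any resizing the
  model needs left to the adapter.
- Generated patches contain their own background, so composition replaces
  only mask-foreground pixels. Default blend is a hard paste; feathered
  blending alpha-ramps the mask interior within a configurable radius.
  Instances are pasted back-to-front by the camera depth of each leaf's
  centroid.
- Backgrounds are multi-octave value noise through a soil color ramp —
  a stand-in for photographed soil/pot backgrounds, which can be supplied as
  image files instead.
- The adversarial (E[log D_real] + E[log(1 − D_fake)]) and L1 objectives are
  pure array computations over given discriminator outputs; the default
  combination weights them 0.01 and 1. No network is instantiated here —
  training loops live outside this package by design.

## Evaluation

- Matching is greedy: predictions in descending score, each taking the
  unmatched ground truth of highest IoU if that IoU ≥ τ; ties break to the
  lower index, making reports deterministic. On realistic prediction sets
  (perturbed ground truths plus spurious extras) the greedy match count
  agrees with the optimal assignment ≥ 95 % of the time (tested against a
  Hungarian oracle); greedy is the contract, the oracle is diagnostic.
- Two AP variants: "precision" (matched / total predictions, pooled across
  images, ×100) matching the plain reading of "percentage of correctly
  predicted instances", and 101-point interpolated COCO AP. The variant is
  recorded in every report; pooled-across-images is the default, with
  per-image counts reported alongside.
- Foreground MAE restricts the mean absolute difference to the union of
  *ground-truth* leaf masks — never prediction masks — so fidelity is scored
  on exactly the pixels that matter and is independent of segmenter quality.

## Synthetic presets and what passing tests show

The bundled grammars are deliberately small stand-ins, not reproductions of
any species-calibrated rule set: `rosette` places exactly 8 rhombus leaves at
the golden divergence angle (137.5°) with per-leaf pitch variation — a
deterministic fixture whose leaf count is derivable by counting placeholder
occurrences — and `shoot` is a stochastic branching axis whose leaf count
varies by seed (typically ~15–30 at 8 iterations). They exercise every code
path (hierarchy, occlusion, stochasticity, parametric rules) at desk scale.
What they do not emulate: measured leaf-shape variation, self-bending blades,
specular/shadowed appearance, camera noise. Tests passing on these presets
certify the *mechanisms* (decomposition, occlusion handling, determinism,
lossless export), not photorealism or downstream segmenter accuracy on real
crops.

Default problem sizes — 512² images, ≤ 10 images per run, ≤ 50-model
rasterizer sweeps at 32² — were chosen so the full suite and the acceptance
script each complete in seconds while still covering every stage.

## Degenerate inputs and edge behavior

- Empty models, zero-pixel cameras, unbalanced brackets, polygons with < 3
  vertices, arity-mismatched rule applications, discriminator outputs at 0/1,
  and empty foregrounds all raise typed errors naming the problem.
- `mask_iou` of two empty masks is 0 by convention. AP with zero predictions
  is reported as 0 with a warning (undefined as a ratio).
- COCO export: uncompressed column-major RLE is the default and always
  lossless; polygon mode traces exact pixel-corner boundaries and is exact
  for hole-free instances (holes are filled on encode, as is common COCO
  practice). Amodal masks go to a parallel `.amodal.json` so the visible
  file stays standard-compliant. Images are PNG to keep round trips exact.

## Known limitations

- No context-sensitive or environmentally coupled L-systems; no tropism.
- Leaf blades are flat/fanned polygons; no curvature model.
- The texture generator is a visual approximation — sufficient for pipeline
  development and mask-consistency experiments, not a substitute for a
  trained generator when photorealism matters.
- The refinement stage is a pluggable interface (identity by default); this
  package constructs its training pairs but does not train the refiner.
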