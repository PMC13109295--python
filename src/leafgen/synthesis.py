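"""Mask-to-texture generation, cut-and-paste composition, and GAN objectives.

The image pipeline turns per-leaf mask patches into textured leaf patches and
pastes them over a background, back-to-front:

* A :class:`TextureGenerator` maps a mask patch to an RGB patch of identical
  shape. The default :class:`ProceduralTextureGenerator` is a deterministic,
  seedable generator — base color shaded by distance-to-boundary (rim
  darkening), a midrib plus secondary vein skeleton along the mask's
  principal axis, and seeded speckle noise — so the whole pipeline runs with
  no trained network. A trained image-to-image model (e.g. a Pix2Pix leaf
  generator) slots in through the same interface; see
  :class:`TextureGeneratorAdapter`.
* :func:`compose` implements the composition function: generated patches
  include both leaf and patch-background pixels, so only the pixels where
  the mask is 1 are blended into the frame.
* :func:`build_refinement_pairs` constructs (leaf-replaced, original) image
  pairs from an extraction archive — the self-supervised training data a
  downstream image refiner consumes. The refiner itself is a pluggable
  callable, identity by default.
* :func:`cgan_loss` / :func:`l1_loss` / :func:`total_objective` are the
  adversarial and reconstruction objectives as pure array computations
  (discriminator outputs are given; no network is instantiated here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .render import MaskPatch

__all__ = [
    "PatchPair",
    "ProceduralLeafStyle",
    "TextureGenerator",
    "ProceduralTextureGenerator",
    "TextureGeneratorAdapter",
    "CompositionConfig",
    "PairExtractionArchive",
    "ArchiveRecord",
    "procedural_texture",
    "compose",
    "build_refinement_pairs",
    "cgan_loss",
    "l1_loss",
    "total_objective",
]


@dataclass(frozen=True)
class PatchPair:
    """A mask patch with its paired texture patch."""

    mask: MaskPatch
    texture: np.ndarray  # HxWx3 uint8
    source: str = "synthetic"  # "real" | "synthetic"

    def __post_init__(self):
        if self.texture.shape[:2] != self.mask.mask.shape:
            raise ValueError("mask and texture shapes differ")
        if self.source not in ("real", "synthetic"):
            raise ValueError(f"source must be 'real' or 'synthetic', got {self.source!r}")


@dataclass(frozen=True)
class ProceduralLeafStyle:
    """Parameters of the deterministic leaf-texture generator.

    Colors are 8-bit RGB. ``vein_density`` controls how many secondary veins
    branch off the midrib per pixel of midrib length; ``rim_darkening`` in
    [0, 1] scales how much the leaf darkens toward its boundary.
    """

    base_color: tuple[int, int, int] = (58, 122, 48)
    base_jitter: float = 12.0
    vein_color: tuple[int, int, int] = (120, 170, 100)
    vein_density: float = 0.08
    rim_darkening: float = 0.45
    noise_amplitude: float = 10.0
    background_color: tuple[int, int, int] = (38, 28, 20)

    def __post_init__(self):
        for c in (*self.base_color, *self.vein_color, *self.background_color):
            if not 0 <= c <= 255:
                raise ValueError("colors must be 8-bit")
        if not 0 <= self.rim_darkening <= 1:
            raise ValueError("rim_darkening must be in [0,1]")
        if self.vein_density < 0 or self.noise_amplitude < 0:
            raise ValueError("vein density and noise amplitude must be >= 0")


class TextureGenerator(Protocol):
    """Mask patch -> RGB texture patch of identical spatial shape."""

    name: str

    def generate(self, mask: MaskPatch) -> np.ndarray: ...


def procedural_texture(
    mask: MaskPatch, style: ProceduralLeafStyle | None = None, seed: int = 0
) -> np.ndarray:
    """Deterministic leaf texture for a mask patch.

    Inside the mask: the base color, darkened toward the boundary by the
    normalized Euclidean distance transform, with a midrib and secondary
    veins drawn along the mask's principal axis and seeded speckle noise.
    Outside: the style's background color. Deterministic given
    ``(mask, style, seed)``.
    """
    style = style or ProceduralLeafStyle()
    m = np.asarray(mask.mask, bool)
    if not m.any():
        raise ValueError("empty mask patch")
    h, w = m.shape
    rng = np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, mask.instance_id)))

    out = np.empty((h, w, 3), dtype=float)
    out[:] = style.background_color

    # Rim darkening from the distance transform, normalized to [0,1].
    dist = ndimage.distance_transform_edt(m)
    dmax = dist.max()
    depth = dist / dmax if dmax > 0 else dist
    base = np.asarray(style.base_color, float) + rng.normal(0.0, style.base_jitter, 3)
    shade = 1.0 - style.rim_darkening * (1.0 - depth)
    inside = np.where(m)
    out[inside] = base[None, :] * shade[inside][:, None]

    # Vein skeleton along the principal axis of the mask pixels.
    if style.vein_density > 0:
        ys, xs = np.nonzero(m)
        pts = np.stack([xs, ys], axis=1).astype(float)
        centroid = pts.mean(axis=0)
        cov = np.cov((pts - centroid).T) if len(pts) > 1 else np.eye(2)
        evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
        axis = evecs[:, int(np.argmax(evals))]
        half_len = float(np.abs((pts - centroid) @ axis).max())
        perp = np.array([-axis[1], axis[0]])
        vein = np.zeros((h, w), bool)
        ts = np.linspace(-half_len, half_len, max(2, int(4 * half_len)))
        for t in ts:  # midrib
            x, y = centroid + t * axis
            xi, yi = int(round(x)), int(round(y))
            if 0 <= yi < h and 0 <= xi < w:
                vein[yi, xi] = True
        n_secondary = rng.poisson(style.vein_density * max(1.0, 2 * half_len))
        for _ in range(int(n_secondary)):
            t0 = rng.uniform(-half_len, half_len)
            sgn = rng.choice([-1.0, 1.0])
            length = rng.uniform(0.2, 0.6) * half_len
            direction = 0.55 * axis * np.sign(t0 if t0 != 0 else 1.0) * -1 + sgn * perp
            direction = direction / np.linalg.norm(direction)
            for u in np.linspace(0, length, max(2, int(2 * length))):
                x, y = centroid + t0 * axis + u * direction
                xi, yi = int(round(x)), int(round(y))
                if 0 <= yi < h and 0 <= xi < w:
                    vein[yi, xi] = True
        vein &= m
        out[vein] = 0.5 * out[vein] + 0.5 * np.asarray(style.vein_color, float)

    if style.noise_amplitude > 0:
        noise = rng.normal(0.0, style.noise_amplitude, (h, w, 1))
        out[m] = out[m] + noise[m][:, None].reshape(-1, 1) * np.ones((1, 3))

    return np.clip(np.round(out), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class ProceduralTextureGenerator:
    """Default :class:`TextureGenerator`: wraps :func:`procedural_texture`."""

    style: ProceduralLeafStyle = field(default_factory=ProceduralLeafStyle)
    seed: int = 0
    name: str = "procedural"

    def generate(self, mask: MaskPatch) -> np.ndarray:
        return procedural_texture(mask, self.style, self.seed)


@dataclass(frozen=True)
class TextureGeneratorAdapter:
    """Adapter slotting an arbitrary image-to-image callable into the
    :class:`TextureGenerator` interface.

    ``fn`` receives the binary mask patch (HxW uint8) and must return an RGB
    patch of the same spatial shape; any resizing a trained model needs
    (e.g. to a fixed 256x256 input) is the callable's responsibility.
    """

    fn: Callable[[np.ndarray], np.ndarray]
    name: str = "adapter"

    def generate(self, mask: MaskPatch) -> np.ndarray:
        out = np.asarray(self.fn(mask.mask))
        if out.shape[:2] != mask.mask.shape or out.ndim != 3 or out.shape[2] != 3:
            raise ValueError(
                f"texture generator {self.name!r} returned shape {out.shape}, "
                f"expected {(*mask.mask.shape, 3)}"
            )
        return out


@dataclass(frozen=True)
class CompositionConfig:
    """How instances are blended into the frame."""

    blend: str = "hard"  # "hard" | "feathered"
    feather_radius: int = 0
    depth_order: tuple[int, ...] | None = None  # back-to-front instance ids

    def __post_init__(self):
        if self.blend not in ("hard", "feathered"):
            raise ValueError(f"blend must be 'hard' or 'feathered', got {self.blend!r}")
        if self.feather_radius < 0:
            raise ValueError("feather radius must be >= 0")


def compose(
    masks: Sequence[MaskPatch],
    textures: Sequence[np.ndarray],
    background: np.ndarray,
    cfg: CompositionConfig | None = None,
) -> np.ndarray:
    """Paste textured instances over a background, back-to-front.

    Only pixels where an instance's mask is 1 are replaced (the generated
    patches contain their own background, which is discarded); in feathered
    mode the mask interior within ``feather_radius`` of the boundary is
    alpha-blended instead of hard-replaced. Pixels outside every mask are
    bit-identical to the input background.
    """
    cfg = cfg or CompositionConfig()
    if len(masks) != len(textures):
        raise ValueError(f"{len(masks)} masks but {len(textures)} textures")
    bg = np.asarray(background)
    if bg.ndim != 3 or bg.shape[2] != 3:
        raise ValueError("background must be HxWx3")
    h, w = bg.shape[:2]
    out = bg.astype(float).copy()

    order = list(range(len(masks)))
    if cfg.depth_order is not None:
        ids = [m.instance_id for m in masks]
        if sorted(cfg.depth_order) != sorted(ids):
            raise ValueError("depth_order must be a permutation of the composited ids")
        by_id = {m.instance_id: i for i, m in enumerate(masks)}
        order = [by_id[k] for k in cfg.depth_order]

    for i in order:
        patch, tex = masks[i], np.asarray(textures[i], float)
        if tex.shape[:2] != patch.mask.shape:
            raise ValueError(f"texture {i} shape {tex.shape[:2]} != mask {patch.mask.shape}")
        x0, y0, x1, y1 = patch.bbox
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            raise ValueError(f"bbox {patch.bbox} outside background {h}x{w}")
        m = np.asarray(patch.mask, bool)
        if cfg.blend == "feathered" and cfg.feather_radius > 0:
            dist = ndimage.distance_transform_edt(m)
            alpha = np.clip(dist / (cfg.feather_radius + 1.0), 0.0, 1.0)
            alpha[~m] = 0.0
            region = out[y0:y1, x0:x1]
            out[y0:y1, x0:x1] = alpha[..., None] * tex + (1 - alpha[..., None]) * region
        else:
            region = out[y0:y1, x0:x1]
            region[m] = tex[m]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Extraction archives and refinement pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchiveRecord:
    """One extracted (mask, texture) pair from a source image."""

    source_image_id: str
    mask: np.ndarray  # HxW binary patch
    texture: np.ndarray  # HxWx3 uint8
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1) in the source image
    prompt: str = "leaf"
    score: float = 1.0

    def __post_init__(self):
        if self.texture.shape[:2] != self.mask.shape:
            raise ValueError("mask/texture shape mismatch in archive record")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("detector score must be in [0,1]")


@dataclass
class PairExtractionArchive:
    """On-disk schema for externally produced segmenter outputs.

    Layout: one directory per source image holding ``mask_####.png`` /
    ``texture_####.png`` plus ``index.json`` with bbox, prompt and detector
    score per record. This is the interchange format a text-prompted
    foundation segmenter's leaf extractions are written in; the package only
    reads and writes the schema, it never runs such a model.
    """

    records: list[ArchiveRecord] = field(default_factory=list)

    def by_image(self) -> dict[str, list[ArchiveRecord]]:
        out: dict[str, list[ArchiveRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.source_image_id, []).append(rec)
        return out

    def save(self, root: str | Path) -> None:
        root = Path(root)
        for image_id, recs in self.by_image().items():
            d = root / image_id
            d.mkdir(parents=True, exist_ok=True)
            index = []
            for i, rec in enumerate(recs):
                Image.fromarray((rec.mask.astype(np.uint8)) * 255).save(d / f"mask_{i:04d}.png")
                Image.fromarray(rec.texture).save(d / f"texture_{i:04d}.png")
                index.append(
                    {"bbox": list(rec.bbox), "prompt": rec.prompt, "score": rec.score}
                )
            (d / "index.json").write_text(json.dumps(index, indent=1))

    @classmethod
    def load(cls, root: str | Path) -> "PairExtractionArchive":
        root = Path(root)
        records = []
        for d in sorted(p for p in root.iterdir() if p.is_dir()):
            index = json.loads((d / "index.json").read_text())
            for i, meta in enumerate(index):
                mask = np.asarray(Image.open(d / f"mask_{i:04d}.png")) > 127
                tex = np.asarray(Image.open(d / f"texture_{i:04d}.png").convert("RGB"))
                records.append(
                    ArchiveRecord(
                        source_image_id=d.name,
                        mask=mask.astype(np.uint8),
                        texture=tex,
                        bbox=tuple(meta["bbox"]),
                        prompt=meta.get("prompt", "leaf"),
                        score=float(meta.get("score", 1.0)),
                    )
                )
        return cls(records=records)


def build_refinement_pairs(
    archive: PairExtractionArchive,
    gen: TextureGenerator,
    source_images: dict[str, np.ndarray],
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Construct (leaf-replaced image, original image) training pairs.

    For each source image, every extracted leaf region is overwritten with
    the texture the generator produces from its mask (hard blend). The
    returned pairs are the aligned input/target images an external
    refinement model trains on; images with no records come back unchanged.
    """
    pairs = []
    by_image = archive.by_image()
    for image_id in sorted(source_images):
        original = np.asarray(source_images[image_id])
        recs = by_image.pop(image_id, [])
        patches, textures = [], []
        for rec in recs:
            patch = MaskPatch(
                instance_id=0, mask=np.asarray(rec.mask, np.uint8), bbox=rec.bbox
            )
            patches.append(patch)
            textures.append(gen.generate(patch))
        replaced = compose(patches, textures, original, CompositionConfig(blend="hard"))
        pairs.append((replaced, original.astype(np.uint8)))
    if by_image:
        missing = sorted(by_image)
        raise ValueError(f"archive references missing source image(s): {missing}")
    return pairs


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------


def cgan_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Conditional-adversarial objective on given discriminator outputs:
    ``mean(log d_real) + mean(log(1 - d_fake))``.

    Both arrays must lie strictly in (0, 1); the value is always <= 0, with
    the supremum 0 approached only by a perfect discriminator.
    """
    d_real = np.asarray(d_real, float)
    d_fake = np.asarray(d_fake, float)
    for name, arr in (("d_real", d_real), ("d_fake", d_fake)):
        if arr.size == 0:
            raise ValueError(f"{name} is empty")
        if np.any(arr <= 0.0) or np.any(arr >= 1.0):
            raise ValueError(f"{name} values must be strictly in (0,1)")
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def l1_loss(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute difference over all pixels and channels."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def total_objective(cgan: float, l1: float, w_gan: float = 0.01, w_l1: float = 1.0) -> float:
    """Weighted training objective; the defaults weight the adversarial term
    by 0.01 and the L1 reconstruction term by 1."""
    if w_gan < 0 or w_l1 < 0:
        raise ValueError("weights must be >= 0")
    return w_gan * cgan + w_l1 * l1
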