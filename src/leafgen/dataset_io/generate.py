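"""End-to-end dataset generation: grammar -> masks -> textures -> images.

For each requested image the pipeline derives the hierarchical plant string,
interprets it into a labeled 3D model, rasterizes visible (and optionally
amodal) instance masks, crops per-leaf patches, textures them, and composes
the final plant image over a background — recording full provenance so any
record can be regenerated bit-identically from its config and seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from ..lsystem import Grammar, expand_hierarchical, load_grammar
from ..render import CameraSpec, InstanceMaskSet, crop_patches, render_masks
from ..synthesis import (
    CompositionConfig,
    ProceduralLeafStyle,
    ProceduralTextureGenerator,
    TextureGenerator,
    compose,
)
from ..turtle3d import interpret
from .backgrounds import BackgroundStyle, load_background, make_background

__all__ = ["DatasetRecord", "GenerationConfig", "generate_dataset", "preset_path"]

log = logging.getLogger("leafgen")

_PRESET_DIR = Path(__file__).resolve().parent.parent / "presets"


def preset_path(name: str) -> Path:
    """Path of a bundled preset grammar (``rosette`` or ``shoot``)."""
    p = _PRESET_DIR / f"{name}.lsys"
    if not p.exists():
        available = sorted(q.stem for q in _PRESET_DIR.glob("*.lsys"))
        raise FileNotFoundError(f"no preset {name!r}; available: {available}")
    return p


@dataclass
class DatasetRecord:
    """One generated (image, instance-mask) pair with its provenance."""

    image_id: str
    image: np.ndarray | None
    masks: InstanceMaskSet
    provenance: dict = field(default_factory=dict)


@dataclass
class GenerationConfig:
    """Everything needed to (re)generate a dataset deterministically."""

    grammar: str | Path = "rosette"  # preset name or .lsys path
    iterations: int = 10
    count: int = 1
    seed: int = 0
    image_size: tuple[int, int] = (512, 512)
    camera_extent: float = 6.0
    mask_mode: str = "both"  # visible | amodal | both
    pad: int = 2
    min_area: int = 16
    style: ProceduralLeafStyle = field(default_factory=ProceduralLeafStyle)
    background_style: BackgroundStyle = field(default_factory=BackgroundStyle)
    background_path: str | None = None
    composition: CompositionConfig = field(default_factory=CompositionConfig)
    output_dir: str | Path | None = None

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")

    def resolve_grammar_path(self) -> Path:
        p = Path(self.grammar)
        if p.suffix == ".lsys" and p.exists():
            return p
        return preset_path(str(self.grammar))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        simple = {
            "grammar", "iterations", "count", "seed", "camera_extent",
            "mask_mode", "pad", "min_area", "background_path", "output_dir",
        }
        for key, value in raw.items():
            if key in simple:
                kwargs[key] = value
            elif key == "image_size":
                kwargs[key] = tuple(value)
            elif key == "style":
                kwargs[key] = ProceduralLeafStyle(**{
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                })
            elif key == "background_style":
                if "ramp" in value:
                    value = dict(value, ramp=tuple(tuple(c) for c in value["ramp"]))
                kwargs[key] = BackgroundStyle(**value)
            elif key == "composition":
                kwargs[key] = CompositionConfig(**value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


def _record_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 0xDA7A, index))
    return int(ss.generate_state(1)[0] % (2**31))


def _leaf_depth_order(model, cam: CameraSpec) -> list[int]:
    """Back-to-front leaf instance ids by centroid camera depth."""
    depths = {}
    for organ in model.leaves:
        verts = organ.vertex_array
        if len(verts) == 0:
            continue
        _, depth = cam.project(verts.mean(axis=0, keepdims=True))
        depths[organ.instance_id] = float(depth[0])
    return sorted(depths, key=lambda k: -depths[k])  # farthest first


def generate_one(
    grammar: Grammar,
    cfg: GenerationConfig,
    seed: int,
    image_id: str,
    texture_generator: TextureGenerator | None = None,
) -> DatasetRecord:
    """Run the full pipeline for a single record seed."""
    s = expand_hierarchical(grammar, cfg.iterations, seed)
    model = interpret(
        s, angle=grammar.default_angle, step=grammar.default_step, width=0.06
    )
    cam = CameraSpec.top_down(image_size=cfg.image_size, extent=cfg.camera_extent)
    masks = render_masks(model, cam, mode=cfg.mask_mode)
    patches = crop_patches(masks, pad=cfg.pad, min_area=cfg.min_area)

    gen = texture_generator or ProceduralTextureGenerator(style=cfg.style, seed=seed)
    textures = [gen.generate(p) for p in patches]

    h, w = cfg.image_size
    if cfg.background_path:
        background = load_background(cfg.background_path, size=(h, w))
    else:
        background = make_background(h, w, cfg.background_style, seed=seed)

    order = [k for k in _leaf_depth_order(model, cam) if k in {p.instance_id for p in patches}]
    comp_cfg = replace(cfg.composition, depth_order=tuple(order))
    image = compose(patches, textures, background, comp_cfg)

    grammar_hash = hashlib.sha256(
        cfg.resolve_grammar_path().read_bytes()
    ).hexdigest()[:16]
    provenance = {
        "grammar": str(cfg.grammar),
        "grammar_sha256_16": grammar_hash,
        "iterations": cfg.iterations,
        "seed": seed,
        "image_size": list(cfg.image_size),
        "camera_extent": cfg.camera_extent,
        "mask_mode": cfg.mask_mode,
        "pad": cfg.pad,
        "min_area": cfg.min_area,
    }
    return DatasetRecord(image_id=image_id, image=image, masks=masks, provenance=provenance)


def generate_dataset(
    cfg: GenerationConfig,
    texture_generator: TextureGenerator | None = None,
) -> list[DatasetRecord]:
    """Generate ``cfg.count`` records with seeds split deterministically from
    ``cfg.seed``; identical configs yield bit-identical datasets."""
    grammar = load_grammar(cfg.resolve_grammar_path())
    records = []
    for i in range(cfg.count):
        seed_i = _record_seed(cfg.seed, i)
        image_id = f"plant_{i:04d}"
        log.info("record %s: seed=%d grammar=%s", image_id, seed_i, cfg.grammar)
        try:
            rec = generate_one(grammar, cfg, seed_i, image_id, texture_generator)
        except Exception as exc:
            raise RuntimeError(f"record {i} ({image_id}) failed: {exc}") from exc
        records.append(rec)
    return records
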