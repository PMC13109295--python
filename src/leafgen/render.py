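"""Occlusion-aware rasterization of plant models into per-leaf instance masks.

A plant model is projected through a camera (orthographic by default — the
rosette datasets are photographed top-down — or perspective for shoot-like
plants) and scanline-rasterized with a per-pixel z-buffer over all organs.
The label image records the frontmost *leaf* instance per pixel; stem and
branch geometry occludes but labels 0. Two mask flavors are produced:

* **visible** masks — what a photograph shows: ``visible[k] = {label == k}``;
  pairwise disjoint, and their union is exactly the leaf foreground.
* **amodal** masks — each organ rasterized alone, no z-test against the rest
  of the plant: the full projected extent including occluded parts.

Masks are binary {0,1}, row-major with the origin at the top-left pixel;
pixel centers sit at (col + 0.5, row + 0.5). Bounding boxes are 0-based and
half-open (x0, y0, x1, y1), matching COCO conventions downstream. Depth ties
between exactly coplanar leaves go to the lower instance id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .turtle3d import OrganMesh, PlantModel

__all__ = [
    "CameraSpec",
    "LightSpec",
    "InstanceMaskSet",
    "MaskPatch",
    "RenderError",
    "render_masks",
    "crop_patches",
    "shaded_preview",
]


class RenderError(ValueError):
    pass


@dataclass(frozen=True)
class CameraSpec:
    """Camera pose and projection.

    For orthographic projection ``scale`` is world units per pixel; for
    perspective it is the vertical field of view in degrees.
    """

    image_size: tuple[int, int] = (512, 512)  # (height, width)
    projection: str = "orthographic"
    eye: tuple[float, float, float] = (0.0, 0.0, 10.0)
    look_at: tuple[float, float, float] = (0.0, 0.0, 0.0)
    up_hint: tuple[float, float, float] = (0.0, 1.0, 0.0)
    scale: float = 0.02

    def __post_init__(self):
        h, w = self.image_size
        if h < 1 or w < 1:
            raise RenderError("image size must be >= 1 pixel")
        if self.projection not in ("orthographic", "perspective"):
            raise RenderError(f"unknown projection {self.projection!r}")
        if np.allclose(self.eye, self.look_at):
            raise RenderError("camera eye and look_at coincide")
        if self.scale <= 0:
            raise RenderError("camera scale must be positive")

    @staticmethod
    def top_down(image_size=(512, 512), extent: float = 10.0, height: float = 10.0) -> "CameraSpec":
        """Orthographic camera on the -Z axis framing ``extent`` world units."""
        return CameraSpec(
            image_size=image_size,
            projection="orthographic",
            eye=(0.0, 0.0, height),
            look_at=(0.0, 0.0, 0.0),
            up_hint=(0.0, 1.0, 0.0),
            scale=extent / image_size[1],
        )

    def view_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """World -> camera rotation and the eye translation.

        Camera axes: x right, y up (in image terms, before the row flip),
        z toward the scene (depth increases away from the eye).
        """
        eye = np.asarray(self.eye, float)
        fwd = np.asarray(self.look_at, float) - eye
        fwd = fwd / np.linalg.norm(fwd)
        up = np.asarray(self.up_hint, float)
        right = np.cross(fwd, up)
        if np.linalg.norm(right) < 1e-12:
            up = np.array([0.0, 0.0, 1.0]) if abs(fwd[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
            right = np.cross(fwd, up)
        right = right / np.linalg.norm(right)
        cam_up = np.cross(right, fwd)
        rot = np.stack([right, cam_up, fwd])  # rows
        return rot, eye

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project Nx3 world points to pixel coordinates (x=col, y=row) and depth."""
        rot, eye = self.view_matrix()
        cam = (points - eye) @ rot.T
        h, w = self.image_size
        depth = cam[:, 2]
        if self.projection == "orthographic":
            px = cam[:, 0] / self.scale + w / 2.0
            py = h / 2.0 - cam[:, 1] / self.scale
        else:
            f = (h / 2.0) / np.tan(np.radians(self.scale) / 2.0)
            z = np.where(np.abs(depth) < 1e-9, 1e-9, depth)
            px = cam[:, 0] * f / z + w / 2.0
            py = h / 2.0 - cam[:, 1] * f / z
        return np.stack([px, py], axis=1), depth


@dataclass(frozen=True)
class LightSpec:
    """Directional light for the shaded debug preview (masks ignore light)."""

    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    ambient: float = 0.2

    def __post_init__(self):
        d = np.asarray(self.direction, float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
            raise RenderError("light direction must be a unit vector")


@dataclass
class InstanceMaskSet:
    """Per-instance binary masks with the label image and tight boxes."""

    label_image: np.ndarray  # HxW int, 0 = background/stem, k = frontmost leaf
    visible_masks: dict[int, np.ndarray]
    amodal_masks: dict[int, np.ndarray] = field(default_factory=dict)
    bboxes: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)
    visibility: dict[int, float] = field(default_factory=dict)

    @property
    def image_size(self) -> tuple[int, int]:
        return self.label_image.shape

    @property
    def instance_ids(self) -> list[int]:
        return sorted(self.visible_masks)


@dataclass(frozen=True)
class MaskPatch:
    """A per-instance mask crop: the currency of texture generation."""

    instance_id: int
    mask: np.ndarray  # binary patch
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1) in the parent image
    pad: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _rasterize_triangle(v2: np.ndarray, depth: np.ndarray, h: int, w: int):
    """Coverage and interpolated depth of one projected triangle.

    Returns (rows, cols, z) for covered pixel centers, or None. Edge pixels
    use an inclusive barycentric test; masks are hard-labeled, no AA.
    """
    x0 = max(int(np.floor(v2[:, 0].min() - 0.5)), 0)
    x1 = min(int(np.ceil(v2[:, 0].max() - 0.5)) + 1, w)
    y0 = max(int(np.floor(v2[:, 1].min() - 0.5)), 0)
    y1 = min(int(np.ceil(v2[:, 1].max() - 0.5)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    px, py = np.meshgrid(xs, ys)

    (ax, ay), (bx, by), (cx, cy) = v2
    area = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    if abs(area) < 1e-12:
        return None
    w0 = ((bx - px) * (cy - py) - (by - py) * (cx - px)) / area
    w1 = ((cx - px) * (ay - py) - (cy - py) * (ax - px)) / area
    w2 = 1.0 - w0 - w1
    eps = 1e-9
    inside = (w0 >= -eps) & (w1 >= -eps) & (w2 >= -eps)
    if not inside.any():
        return None
    z = w0 * depth[0] + w1 * depth[1] + w2 * depth[2]
    rr, cc = np.nonzero(inside)
    return rr + y0, cc + x0, z[rr, cc]


def _organ_coverage(organ: OrganMesh, cam: CameraSpec, h: int, w: int):
    """Yield per-triangle (rows, cols, depth) hits for one organ."""
    verts = organ.vertex_array
    if len(verts) == 0:
        return
    v2, depth = cam.project(verts)
    for tri in organ.triangle_array:
        if cam.projection == "perspective" and np.any(depth[tri] <= 1e-9):
            continue  # behind the eye
        hit = _rasterize_triangle(v2[tri], depth[tri], h, w)
        if hit is not None:
            yield hit


def _tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1


def render_masks(
    model: PlantModel, cam: CameraSpec, mode: str = "both"
) -> InstanceMaskSet:
    """Rasterize *model* into an :class:`InstanceMaskSet`.

    ``mode`` selects ``visible``, ``amodal``, or ``both``. The z-buffer runs
    over every organ regardless of mode, so stems occlude leaves correctly.
    """
    if mode not in ("visible", "amodal", "both"):
        raise RenderError(f"unknown mask mode {mode!r}")
    if not model.organs or model.triangle_count() == 0:
        raise RenderError("empty model: nothing to render")
    h, w = cam.image_size

    zbuf = np.full((h, w), np.inf)
    label = np.zeros((h, w), dtype=np.int32)
    amodal: dict[int, np.ndarray] = {}
    amodal_counts: dict[int, int] = {}

    # Ascending instance id + strict depth test => lower id wins exact ties.
    for organ in sorted(model.organs, key=lambda o: o.instance_id):
        is_leaf = organ.organ_class == "leaf"
        cover = np.zeros((h, w), dtype=bool) if is_leaf else None
        for rr, cc, z in _organ_coverage(organ, cam, h, w):
            closer = z < zbuf[rr, cc]
            if closer.any():
                r2, c2 = rr[closer], cc[closer]
                zbuf[r2, c2] = z[closer]
                label[r2, c2] = organ.instance_id if is_leaf else 0
            if cover is not None:
                cover[rr, cc] = True
        if cover is not None:
            amodal_counts[organ.instance_id] = int(cover.sum())
            if mode in ("amodal", "both"):
                amodal[organ.instance_id] = cover.astype(np.uint8)

    visible: dict[int, np.ndarray] = {}
    bboxes: dict[int, tuple[int, int, int, int]] = {}
    visibility: dict[int, float] = {}
    for organ in model.leaves:
        k = organ.instance_id
        vis = (label == k).astype(np.uint8)
        n_vis = int(vis.sum())
        n_amodal = amodal_counts.get(k, 0)
        visibility[k] = n_vis / n_amodal if n_amodal else 0.0
        if mode in ("visible", "both"):
            visible[k] = vis
            if n_vis:
                bboxes[k] = _tight_bbox(vis)
    if mode == "amodal":
        for k, m in amodal.items():
            if m.any():
                bboxes[k] = _tight_bbox(m)

    return InstanceMaskSet(
        label_image=label,
        visible_masks=visible,
        amodal_masks=amodal,
        bboxes=bboxes,
        visibility=visibility,
    )


def crop_patches(
    masks: InstanceMaskSet,
    pad: int = 0,
    *,
    min_area: int = 16,
    use_amodal: bool = False,
) -> list[MaskPatch]:
    """Crop each instance's mask to its padded tight bounding box.

    Instances with fewer than ``min_area`` pixels are skipped: sub-pixel
    slivers of almost fully occluded leaves poison both texture generation
    and AP evaluation. The default of 16 pixels is configurable.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    h, w = masks.image_size
    source = masks.amodal_masks if use_amodal else masks.visible_masks
    patches = []
    for k in sorted(source):
        mask = source[k]
        area = int(mask.sum())
        if area == 0 or area < min_area:
            continue
        x0, y0, x1, y1 = _tight_bbox(mask)
        x0, y0 = max(0, x0 - pad), max(0, y0 - pad)
        x1, y1 = min(w, x1 + pad), min(h, y1 + pad)
        patches.append(
            MaskPatch(instance_id=k, mask=mask[y0:y1, x0:x1].copy(), bbox=(x0, y0, x1, y1), pad=pad)
        )
    return patches


def shaded_preview(model: PlantModel, cam: CameraSpec, light: LightSpec) -> np.ndarray:
    """Flat-shaded Lambertian grayscale preview (debug visualization).

    Per pixel: ``max(0, n . l) * (1 - ambient) + ambient`` using the face
    normal of the frontmost triangle; background stays 0.
    """
    h, w = cam.image_size
    zbuf = np.full((h, w), np.inf)
    img = np.zeros((h, w))
    ldir = np.asarray(light.direction, float)
    for organ in model.organs:
        verts = organ.vertex_array
        if len(verts) == 0:
            continue
        v2, depth = cam.project(verts)
        for tri in organ.triangle_array:
            a, b, c = verts[tri]
            n = np.cross(b - a, c - a)
            norm = np.linalg.norm(n)
            if norm < 1e-12:
                continue
            n = n / norm
            shade = max(0.0, float(n @ ldir)) * (1 - light.ambient) + light.ambient
            hit = _rasterize_triangle(v2[tri], depth[tri], h, w)
            if hit is None:
                continue
            rr, cc, z = hit
            closer = z < zbuf[rr, cc]
            zbuf[rr[closer], cc[closer]] = z[closer]
            img[rr[closer], cc[closer]] = shade
    return img
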