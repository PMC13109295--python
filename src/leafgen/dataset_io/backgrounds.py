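"""Seeded procedural soil/pot backgrounds.

Multi-octave value noise (coarse random grids bilinearly upsampled and
summed with halving amplitudes) mapped through a soil color ramp. Purely a
stand-in for photographed backgrounds: any PNG/JPEG can be supplied to the
composition step instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["BackgroundStyle", "make_background", "load_background"]


@dataclass(frozen=True)
class BackgroundStyle:
    """Soil ramp and noise parameters; amplitude 0 gives a constant color."""

    ramp: tuple[tuple[int, int, int], ...] = (
        (30, 22, 16),
        (62, 45, 30),
        (96, 74, 52),
        (124, 102, 74),
    )
    octaves: int = 4
    base_cell: int = 8
    noise_amplitude: float = 1.0

    def __post_init__(self):
        if len(self.ramp) < 1:
            raise ValueError("ramp needs at least one color")
        if self.octaves < 1 or self.base_cell < 1:
            raise ValueError("octaves and base_cell must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")


def make_background(
    height: int, width: int, style: BackgroundStyle | None = None, seed: int = 0
) -> np.ndarray:
    """Deterministic HxWx3 uint8 soil background for ``(style, seed)``."""
    if height < 1 or width < 1:
        raise ValueError("background dimensions must be >= 1")
    style = style or BackgroundStyle()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 0xB6)))

    field = np.zeros((height, width))
    if style.noise_amplitude > 0:
        amp = 1.0
        for octave in range(style.octaves):
            cells = style.base_cell * (2**octave)
            gh = max(2, min(height, cells))
            gw = max(2, min(width, cells))
            grid = rng.random((gh, gw))
            field += amp * ndimage.zoom(
                grid, (height / gh, width / gw), order=1, grid_mode=True, mode="nearest"
            )
            amp *= 0.5
        field -= field.min()
        peak = field.max()
        if peak > 0:
            field /= peak
        field = 0.5 + style.noise_amplitude * (field - 0.5)
        field = np.clip(field, 0.0, 1.0)
    else:
        field[:] = 0.5

    ramp = np.asarray(style.ramp, float)
    stops = np.linspace(0.0, 1.0, len(ramp)) if len(ramp) > 1 else np.array([0.0])
    out = np.empty((height, width, 3))
    for c in range(3):
        out[..., c] = np.interp(field, stops, ramp[:, c])
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def load_background(path, size: tuple[int, int] | None = None) -> np.ndarray:
    """Load a user-supplied background image, optionally resizing to (h, w)."""
    from PIL import Image

    img = Image.open(path).convert("RGB")
    if size is not None:
        img = img.resize((size[1], size[0]), Image.BILINEAR)
    return np.asarray(img)
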