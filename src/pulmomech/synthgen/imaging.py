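"""Synthetic alveolar section images.

Renders a septal-wall lattice (square by default; hexagonal for realism
checks) as a bright-field-like grayscale image: bright airspace, darker
tissue, optional solid vessel discs, Gaussian gray-level noise.  For the
square lattice the mean airspace chord along an axis-aligned probe has the
exact closed form ``cell_pitch - wall_thickness``, which anchors the Lm
pipeline tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import draw, morphology

from ..errors import InvalidSpecError
from ..morpho import HistologyImage


@dataclass
class AlveolarImageSpec:
    """Geometry and rendering parameters of a synthetic section."""

    width_px: int = 1024
    height_px: int = 1024
    px_size: float = 1.0        # um per pixel
    cell_pitch: float = 40.0    # um, lattice spacing
    wall_thickness: float = 2.0  # um
    lattice: str = "square"
    origin_offset_um: float = 0.0  # shifts the lattice phase within the field
    vessel_count: int = 0
    vessel_diameter: float = 80.0  # um
    noise_sd: float = 8.0       # gray levels
    tissue_gray: int = 90
    air_gray: int = 220
    seed: int = 0

    def __post_init__(self):
        if self.width_px < 8 or self.height_px < 8:
            raise InvalidSpecError("image too small")
        if self.px_size <= 0:
            raise InvalidSpecError("px_size must be positive")
        if not self.cell_pitch > self.wall_thickness > 0:
            raise InvalidSpecError("require cell_pitch > wall_thickness > 0")
        if self.lattice not in ("square", "hexagonal"):
            raise InvalidSpecError(f"unknown lattice {self.lattice!r}")
        if self.vessel_count < 0 or self.noise_sd < 0:
            raise InvalidSpecError("vessel_count and noise_sd must be >= 0")

    @property
    def theoretical_lm(self) -> float:
        """Closed-form mean airspace chord of the square lattice (um)."""
        return self.cell_pitch - self.wall_thickness


def _square_walls(spec: AlveolarImageSpec) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    pitch = spec.cell_pitch / spec.px_size
    off = spec.origin_offset_um / spec.px_size
    wall = max(int(round(spec.wall_thickness / spec.px_size)), 1)
    mask = np.zeros((h, w), dtype=bool)
    for x0 in np.round(np.arange(off - pitch, w, pitch)).astype(int):
        mask[:, max(x0, 0):max(x0 + wall, 0)] = True
    for y0 in np.round(np.arange(off - pitch, h, pitch)).astype(int):
        mask[max(y0, 0):max(y0 + wall, 0), :] = True
    return mask


def _hex_walls(spec: AlveolarImageSpec) -> np.ndarray:
    """Honeycomb wall lattice drawn edge by edge and thickened by dilation."""
    h, w = spec.height_px, spec.width_px
    s = spec.cell_pitch / spec.px_size / np.sqrt(3.0)  # hexagon side, px
    mask = np.zeros((h, w), dtype=bool)
    dy = 1.5 * s
    dx = np.sqrt(3.0) * s
    for j, y in enumerate(np.arange(-s, h + 2 * s, dy)):
        off = 0.0 if j % 2 == 0 else dx / 2.0
        for x in np.arange(-dx, w + dx, dx):
            cx, cy = x + off, y
            pts = [(cy + s * np.cos(np.pi / 6 + k * np.pi / 3),
                    cx + s * np.sin(np.pi / 6 + k * np.pi / 3)) for k in range(6)]
            for k in range(6):
                r0, c0 = pts[k]
                r1, c1 = pts[(k + 1) % 6]
                rr, cc = draw.line(int(round(r0)), int(round(c0)),
                                   int(round(r1)), int(round(c1)))
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                mask[rr[keep], cc[keep]] = True
    wall = max(int(round(spec.wall_thickness / spec.px_size)), 1)
    if wall > 1:
        mask = morphology.dilation(mask, morphology.disk(wall // 2))
    return mask


def generate_alveolar_image(spec: AlveolarImageSpec) -> HistologyImage:
    """Render the lattice plus ``vessel_count`` non-overlapping vessel discs.

    Vessels are solid tissue discs of ``vessel_diameter``; disc centers are
    drawn uniformly (seeded) with rejection so the requested number of
    distinct vessel components is present before preprocessing.
    """
    tissue = _square_walls(spec) if spec.lattice == "square" else _hex_walls(spec)
    rng = np.random.default_rng(spec.seed)
    r_px = spec.vessel_diameter / (2.0 * spec.px_size)
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < spec.vessel_count and tries < 1000:
        tries += 1
        cy = rng.uniform(r_px + 2, spec.height_px - r_px - 2)
        cx = rng.uniform(r_px + 2, spec.width_px - r_px - 2)
        if all((cy - y)**2 + (cx - x)**2 > (2.5 * r_px)**2 for y, x in centers):
            centers.append((cy, cx))
    if len(centers) < spec.vessel_count:
        raise InvalidSpecError("could not place the requested vessels")
    for cy, cx in centers:
        rr, cc = draw.disk((cy, cx), r_px, shape=tissue.shape)
        tissue[rr, cc] = True

    img = np.where(tissue, float(spec.tissue_gray), float(spec.air_gray))
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return HistologyImage(pixels=img, px_size=spec.px_size)
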