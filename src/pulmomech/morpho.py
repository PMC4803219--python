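"""Alveolar mean linear intercept (Lm) morphometry.

Pipeline: vessel/spurious-structure removal, binarization of the tissue,
skeletonization of the septal walls, and intercept counting on a grid of
probe lines (11 vertical + 9 horizontal by default).  Lm is the mean
airspace chord length along the probes:

    Lm = (summed length of airspace chords) / (number of chords),

where a chord is a maximal air run delimited by a pair of septal
intercepts (open-ended runs at probe ends are excluded).  On an ideal
square lattice of pitch p and wall thickness w this equals p - w, the
interseptal airspace distance.  Larger Lm indicates enlarged
(emphysematous) airspaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
import tifffile
from skimage import filters, morphology

from .errors import (ConfigurationError, EmptyTissueError, InvalidSpecError,
                     UndefinedLmError)


@dataclass
class HistologyImage:
    """Section image with pixel-size calibration and optional exclusion mask."""

    pixels: np.ndarray          # 2-D gray or 3-D RGB
    px_size: float              # um per pixel
    exclusion_mask: np.ndarray | None = None  # True where excluded manually

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.px_size <= 0:
            raise InvalidSpecError("px_size must be positive")
        if self.exclusion_mask is not None:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
            if self.exclusion_mask.shape != self.pixels.shape[:2]:
                raise InvalidSpecError("exclusion mask shape mismatch")

    @property
    def shape(self):
        return self.pixels.shape[:2]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arr = self.pixels
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, arr)
        else:
            PILImage.fromarray(arr).save(path)

    @classmethod
    def load(cls, path: str | Path, px_size: float,
             exclusion_path: str | Path | None = None) -> "HistologyImage":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(PILImage.open(path))
        mask = None
        if exclusion_path is not None:
            m = np.asarray(PILImage.open(exclusion_path))
            if m.ndim == 3:
                m = m[..., 0]
            mask = m > 0
        return cls(pixels=arr, px_size=px_size, exclusion_mask=mask)


@dataclass
class MorphoConfig:
    """Tunable thresholds of the Lm pipeline (lengths/areas in um)."""

    polarity: str = "dark_tissue"       # or "light_tissue"
    vessel_area_um2: float = 5000.0     # opened components above this are vessels
    vessel_opening_radius_um: float = 5.0  # must exceed half the septal wall width
    speck_area_um2: float = 20.0
    vessel_max_frac: float = 0.5        # skip removal if "vessels" exceed this tissue fraction
    margin_frac: float = 0.02           # per-side probe-grid margin
    n_vertical: int = 11
    n_horizontal: int = 9
    colinear_run_px: int = 10           # longer runs = probe-parallel walls


@dataclass
class ProbeGrid:
    """Equally spaced interior probe lines (geometry only, in pixels/um)."""

    v_cols: np.ndarray          # column index of each vertical line
    h_rows: np.ndarray          # row index of each horizontal line
    row_lo: int                 # inclusive extent of vertical lines
    row_hi: int                 # exclusive
    col_lo: int
    col_hi: int
    px_size: float

    @property
    def v_len_px(self) -> int:
        return self.row_hi - self.row_lo

    @property
    def h_len_px(self) -> int:
        return self.col_hi - self.col_lo

    @property
    def total_length(self) -> float:
        """Geometric probe length in um."""
        return (self.v_cols.size * self.v_len_px
                + self.h_rows.size * self.h_len_px) * self.px_size


@dataclass
class LmResult:
    """Probe-grid intercept count and mean linear intercept.

    ``n_intercepts`` counts the interior airspace chords along the probes
    (air runs bounded by septal tissue on both sides, so each chord is
    delimited by a pair of tissue intercepts); ``total_probe_length`` is
    their summed length.  ``n_skeleton_runs`` is the raw count of skeleton
    crossings used for the cross-point audit image.
    """

    n_intercepts: int
    total_probe_length: float   # um of airspace chord length along probes
    Lm: float                   # um
    grid_length: float = float("nan")   # geometric probe length, um
    n_skeleton_runs: int = 0
    n_flagged_runs: int = 0
    intermediates: dict = field(default_factory=dict)


# ----------------------------------------------------------------- stages
def preprocess(image: HistologyImage,
               config: MorphoConfig | None = None) -> np.ndarray:
    """Binary tissue mask with vessels, excluded regions and specks removed.

    Binarization is an automatic global (Otsu) threshold on the grayscale
    (luminance of RGB) with a polarity flag.  Vessels - solid structures much
    wider than any septal wall - are found by a binary opening with a disk of
    ``vessel_opening_radius_um``; opened components larger than
    ``vessel_area_um2`` are dilated back and removed from the tissue mask.
    """
    config = config or MorphoConfig()
    px = image.pixels
    if px.ndim == 3:
        gray = px[..., :3].astype(float) @ np.array([0.2125, 0.7154, 0.0721])
    else:
        gray = px.astype(float)
    if np.ptp(gray) == 0:
        raise EmptyTissueError("image is constant; no tissue to segment")
    thr = filters.threshold_otsu(gray)
    if config.polarity == "dark_tissue":
        tissue = gray < thr
    elif config.polarity == "light_tissue":
        tissue = gray > thr
    else:
        raise ConfigurationError(f"unknown polarity {config.polarity!r}")
    if not tissue.any():
        raise EmptyTissueError("no foreground tissue after binarization")

    px2 = image.px_size**2
    r_px = max(int(round(config.vessel_opening_radius_um / image.px_size)), 1)
    opened = morphology.opening(tissue, morphology.disk(r_px))
    if opened.any():
        labels = morphology.label(opened)
        counts = np.bincount(labels.ravel())
        big = np.flatnonzero(counts * px2 > config.vessel_area_um2)
        big = big[big != 0]
        if big.size:
            cores = np.isin(labels, big)
            vessels = morphology.dilation(cores, morphology.disk(r_px + 1))
            vessels &= tissue
            # a "vessel" covering most of the section is a dense-tissue
            # field, not a vessel: leave it alone
            if vessels.sum() <= config.vessel_max_frac * tissue.sum():
                tissue = tissue & ~vessels
    if image.exclusion_mask is not None:
        tissue = tissue & ~image.exclusion_mask
    min_px = max(int(np.ceil(config.speck_area_um2 / px2)), 1)
    labels = morphology.label(tissue)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_px)
    small = small[small != 0]
    if small.size:
        tissue = tissue & ~np.isin(labels, small)
    if not tissue.any():
        raise EmptyTissueError("no tissue left after cleaning")
    return tissue


def skeletonize_walls(binary: np.ndarray) -> np.ndarray:
    """One-pixel-wide skeleton of the binary septal structure."""
    return morphology.skeletonize(np.asarray(binary, dtype=bool))


def build_grid(shape: tuple, px_size: float,
               config: MorphoConfig | None = None) -> ProbeGrid:
    """Equally spaced probe lines with per-side interior margins.

    ``margin_frac`` of each dimension is kept clear on every side so probes
    never coincide with image borders; placement is deterministic.
    """
    config = config or MorphoConfig()
    h, w = shape
    mh = int(round(config.margin_frac * h))
    mw = int(round(config.margin_frac * w))
    row_lo, row_hi = mh, h - mh
    col_lo, col_hi = mw, w - mw
    if (col_hi - col_lo) < config.n_vertical or (row_hi - row_lo) < config.n_horizontal:
        raise ConfigurationError("image too small for the probe grid")
    v_cols = np.round(np.linspace(col_lo, col_hi - 1, config.n_vertical)).astype(int)
    h_rows = np.round(np.linspace(row_lo, row_hi - 1, config.n_horizontal)).astype(int)
    return ProbeGrid(v_cols=v_cols, h_rows=h_rows, row_lo=row_lo, row_hi=row_hi,
                     col_lo=col_lo, col_hi=col_hi, px_size=px_size)


def _runs(line: np.ndarray):
    """Start/length pairs of maximal True runs in a boolean vector."""
    padded = np.concatenate([[False], line, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends - starts))


def count_intercepts(skeleton: np.ndarray, grid: ProbeGrid,
                     config: MorphoConfig | None = None):
    """Number of skeleton intercepts over all probe lines.

    An intercept is one maximal connected run of skeleton pixels on a probe
    line, so a wall crossing obliquely (spanning several pixels) counts
    once.  Runs longer than ``colinear_run_px`` are probe-parallel walls:
    counted once each and flagged.  Returns (count, n_flagged, crosspoints)
    where crosspoints marks the first pixel of every counted run.
    """
    config = config or MorphoConfig()
    skel = np.asarray(skeleton, dtype=bool)
    cross = np.zeros_like(skel)
    total = 0
    flagged = 0
    for c in grid.v_cols:
        for s, ln in _runs(skel[grid.row_lo:grid.row_hi, c]):
            total += 1
            if ln > config.colinear_run_px:
                flagged += 1
            cross[grid.row_lo + s, c] = True
    for r in grid.h_rows:
        for s, ln in _runs(skel[r, grid.col_lo:grid.col_hi]):
            total += 1
            if ln > config.colinear_run_px:
                flagged += 1
            cross[r, grid.col_lo + s] = True
    return total, flagged, cross


def airspace_probe_length(tissue: np.ndarray, grid: ProbeGrid) -> float:
    """Probe length (um) lying in airspace (non-tissue) pixels."""
    air = ~np.asarray(tissue, dtype=bool)
    n = 0
    for c in grid.v_cols:
        n += int(np.sum(air[grid.row_lo:grid.row_hi, c]))
    for r in grid.h_rows:
        n += int(np.sum(air[r, grid.col_lo:grid.col_hi]))
    return n * grid.px_size


def airspace_chords(tissue: np.ndarray, grid: ProbeGrid):
    """Interior airspace chords along the probe lines.

    A chord is a maximal air run bounded by tissue on both sides; runs
    touching a probe-line end are open-ended (no second intercept) and are
    excluded.  Returns ``(total_length_um, n_chords)``.
    """
    air = ~np.asarray(tissue, dtype=bool)
    n_px = 0
    n_chords = 0

    def consume(line):
        nonlocal n_px, n_chords
        for s, ln in _runs(line):
            if s == 0 or s + ln == line.size:
                continue
            n_px += int(ln)
            n_chords += 1

    for c in grid.v_cols:
        consume(air[grid.row_lo:grid.row_hi, c])
    for r in grid.h_rows:
        consume(air[r, grid.col_lo:grid.col_hi])
    return n_px * grid.px_size, n_chords


def compute_lm(image: HistologyImage,
               config: MorphoConfig | None = None) -> LmResult:
    """Composed pipeline: preprocess, skeletonize, probe grid, Lm.

    Intermediate artifacts (binary, skeleton, cross-point image, grid) are
    attached to the result for audit.
    """
    config = config or MorphoConfig()
    tissue = preprocess(image, config)
    skel = skeletonize_walls(tissue)
    grid = build_grid(tissue.shape, image.px_size, config)
    n_runs, flagged, cross = count_intercepts(skel, grid, config)
    if flagged:
        warnings.warn(f"{flagged} probe-parallel wall run(s) counted once",
                      stacklevel=2)
    length, n = airspace_chords(tissue, grid)
    if n == 0:
        raise UndefinedLmError("no airspace chord crosses the probe grid; "
                               "Lm undefined")
    return LmResult(n_intercepts=n, total_probe_length=length, Lm=length / n,
                    grid_length=grid.total_length, n_skeleton_runs=n_runs,
                    n_flagged_runs=flagged,
                    intermediates={"binary": tissue, "skeleton": skel,
                                   "crosspoints": cross, "grid": grid})
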