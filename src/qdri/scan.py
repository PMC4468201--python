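"""Probe-array geometry, raster planning, frame stitching, margin
segmentation, and replicate-noise figures of merit (SNR, RSD)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage import filters, morphology


@dataclass(frozen=True)
class ProbeArray:
    """7x7 channel array, 6 mm pitch, checkerboard odd/even illumination.

    Channels are numbered 1..49 row-major; the odd parity is the
    checkerboard set containing the corners and the centre (25 channels),
    matching the odd channel numbers.
    """

    rows: int = 7
    cols: int = 7
    pitch_mm: float = 6.0

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def channel_number(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError("channel position outside array")
        return row * self.cols + col + 1

    def parity(self, row: int, col: int) -> str:
        return "odd" if (row + col) % 2 == 0 else "even"

    @property
    def span_mm(self) -> float:
        return self.rows * self.pitch_mm

    def channel_centers_mm(self) -> np.ndarray:
        """(rows, cols, 2) array of (x, y) centres; each channel sits at the
        centre of its pitch cell, origin at the probe's top-left corner."""
        c = np.arange(self.cols) * self.pitch_mm + self.pitch_mm / 2
        r = np.arange(self.rows) * self.pitch_mm + self.pitch_mm / 2
        xx, yy = np.meshgrid(c, r)
        return np.stack([xx, yy], axis=-1)


def parity_split(array: ProbeArray) -> tuple[set, set]:
    """Checkerboard partition of channel numbers into (odd, even) sets."""
    odd, even = set(), set()
    for r in range(array.rows):
        for c in range(array.cols):
            (odd if array.parity(r, c) == "odd" else even).add(array.channel_number(r, c))
    return odd, even


@dataclass(frozen=True)
class RasterPlan:
    """n^2 probe placements on a regular sub-grid of step pitch/n mm."""

    upsample_factor: int
    pitch_mm: float = 6.0

    def __post_init__(self):
        n = self.upsample_factor
        if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
            raise ValueError("upsample factor must be a positive integer")

    @property
    def step_mm(self) -> float:
        return self.pitch_mm / self.upsample_factor

    @property
    def n_placements(self) -> int:
        return self.upsample_factor**2

    def offsets_mm(self) -> list[tuple[float, float]]:
        """Probe displacements in serpentine (boustrophedon) order; stitching
        keys on the values, not this order."""
        n = self.upsample_factor
        out = []
        for j in range(n):
            cols = range(n) if j % 2 == 0 else range(n - 1, -1, -1)
            for i in cols:
                out.append((i * self.step_mm, j * self.step_mm))
        return out

    def offset_indices(self) -> list[tuple[int, int]]:
        n = self.upsample_factor
        return [(i, j) for j in range(n) for i in range(n)]


def plan_raster(upsample_factor: int, pitch_mm: float = 6.0) -> RasterPlan:
    return RasterPlan(upsample_factor, pitch_mm)


@dataclass
class Frame:
    """One full 49-channel snapshot pair at a single probe offset."""

    spectra: np.ndarray  # (49, n_wavelengths) raw per-channel reflectance
    sc_odd: np.ndarray  # self-calibration spectrum for the odd snapshot
    sc_even: np.ndarray
    offset_index: tuple[int, int]  # (i, j) sub-grid indices
    offset_mm: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.spectra.shape[0] != 49:
            raise ValueError("a frame carries 49 tissue channels")

    def channel_grid(self, reducer=None) -> np.ndarray:
        """(7, 7) per-channel scalars (default: band mean of each spectrum)."""
        vals = self.spectra.mean(axis=1) if reducer is None else reducer(self.spectra)
        return vals.reshape(7, 7)


@dataclass
class ParameterMap:
    """(7n, 7n) grid of extracted scalars at pitch 6/n mm."""

    values: np.ndarray
    pitch_mm: float
    label: str = ""
    units: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("parameter map must be 2-D")
        object.__setattr__(self, "values", v)

    @property
    def shape(self):
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        v = self.values
        if self.mask is not None:
            v = v[self.mask]
        return v[np.isfinite(v)]


def stitch(
    values_by_offset: Mapping[tuple[int, int], np.ndarray],
    plan: RasterPlan,
    label: str = "",
    units: str = "",
) -> ParameterMap:
    """Interleave per-offset (7, 7) channel grids into a (7n, 7n) map.

    Channel (r, c) of the frame at sub-offset (i, j) fills map cell
    (r*n + j, c*n + i); every cell is filled exactly once.
    """
    n = plan.upsample_factor
    expected = set(plan.offset_indices())
    got = set(values_by_offset.keys())
    if got != expected:
        missing = expected - got
        extra = got - expected
        raise ValueError(f"offset set mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
    out = np.full((7 * n, 7 * n), np.nan)
    for (i, j), grid in values_by_offset.items():
        grid = np.asarray(grid, dtype=float)
        if grid.shape != (7, 7):
            raise ValueError(f"frame grid at offset {(i, j)} has shape {grid.shape}, want (7, 7)")
        out[j::n, i::n] = grid
    return ParameterMap(out, pitch_mm=plan.step_mm, label=label, units=units)


def unstitch(pmap: ParameterMap, plan: RasterPlan) -> dict[tuple[int, int], np.ndarray]:
    """Exact inverse of :func:`stitch`."""
    n = plan.upsample_factor
    if pmap.values.shape != (7 * n, 7 * n):
        raise ValueError("map shape inconsistent with plan")
    return {(i, j): pmap.values[j::n, i::n].copy() for (i, j) in plan.offset_indices()}


def segment_margin(
    pmap: ParameterMap,
    closing_radius: int = 2,
    min_region_px: int = 16,
) -> np.ndarray:
    """Gradient-magnitude edge detection + morphological closing + hole fill.

    Returns a boolean in-margin mask; an empty result logs a warning and
    returns all-False.
    """
    img = np.nan_to_num(pmap.values, nan=0.0)
    if img.max() <= img.min():
        warnings.warn("featureless map: empty margin mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    grad = filters.sobel(img)
    thr = filters.threshold_otsu(grad)
    edges = grad > thr
    closed = morphology.closing(edges, morphology.disk(closing_radius))
    filled = ndimage.binary_fill_holes(closed)
    mask = morphology.remove_small_objects(filled, max_size=min_region_px - 1)
    # the closed edge band straddles the physical boundary; pull it in by
    # roughly half the edge width
    mask = morphology.erosion(mask, morphology.disk(1))
    if not mask.any():
        warnings.warn("segmentation found no margin region", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    return mask


def snr_db(replicate_stack: np.ndarray, formula: str = "printed") -> np.ndarray:
    """Per-element SNR of a replicate stack (replicates on axis 0).

    ``formula='printed'`` follows the published expression
    ``20*log10(mean/variance)`` verbatim (variance, not standard deviation,
    in the denominator); ``formula='std'`` is the conventional alternative.
    Zero-variance elements return +inf.
    """
    stack = np.asarray(replicate_stack, dtype=float)
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    mean = stack.mean(axis=0)
    var = stack.var(axis=0, ddof=1)
    denom = var if formula == "printed" else np.sqrt(var)
    if formula not in ("printed", "std"):
        raise ValueError("formula must be 'printed' or 'std'")
    with np.errstate(divide="ignore"):
        return np.where(denom > 0, 20.0 * np.log10(np.where(denom > 0, mean / denom, 1.0)), np.inf)


def rsd_percent(replicate_maps: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Relative standard deviation |sigma/mu| across replicates, averaged
    over unmasked pixels, as a percentage.  Zero-mean pixels are masked."""
    stack = np.asarray(replicate_maps, dtype=float)
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    if np.all(stack == stack[0]):
        return 0.0
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    valid = mean != 0
    if mask is not None:
        valid &= mask
    if not valid.any():
        raise ValueError("no valid pixels for RSD")
    return float(np.mean(np.abs(sd[valid] / mean[valid])) * 100.0)
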