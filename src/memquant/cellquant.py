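"""Cell-image quantification: translocation ratios and lipid maps.

Four measurements of where a fluorescent protein (or lipid sensor) sits
in a cell:

* ``membrane_ratio_from_profile`` — a line profile drawn across a cell
  shows two plasma-membrane peaks; the membrane-to-cytosol ratio is
  Fm/Fc with Fm the mean of the two peak intensities and Fc the mean
  intensity strictly between them.
* ``nuclear_ratio`` — nucleus-to-cytoplasm intensity ratio Inuc/Icyto,
  from masks or from >= 5 cross-sectional line profiles.
* ``tirf_timecourse`` — masked mean-intensity time series with the t = 0
  value subtracted, the standard readout of stimulus-evoked membrane
  recruitment under TIRF illumination.
* ``pip2_concentration_map`` — per-pixel two-channel ratio mapped through
  a user-supplied monotone calibration into lipid mole-percent, plus the
  spatial average over a cell mask.

Ratios are computed from mean intensities by default (area-independent);
an integrated-intensity variant of the nuclear ratio is available since
both conventions appear in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InvalidInputError, ProfileShapeError

__all__ = [
    "LineProfile",
    "MembraneTranslocation",
    "NuclearTranslocation",
    "TirfTimecourse",
    "Pip2Map",
    "membrane_ratio_from_profile",
    "nuclear_ratio",
    "nuclear_ratio_from_lines",
    "tirf_timecourse",
    "aggregate_timecourses",
    "pip2_concentration_map",
    "sample_line_profile",
]

DISPLAY_BOUNDS_MOLPCT = (0.0, 1.5)  # default display range for lipid maps
RATIO_FLOOR_FRACTION = 0.01  # denominator pixels below this x masked median are dropped


@dataclass
class LineProfile:
    """Intensity profile along a line across a cell (positions in um)."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise InvalidInputError("positions and intensities must have equal length")
        if self.positions.size < 10:
            raise InvalidInputError("line profile needs at least 10 samples")
        if not np.all(np.diff(self.positions) > 0):
            raise InvalidInputError("positions must be strictly increasing")


@dataclass
class MembraneTranslocation:
    """Membrane-over-cytosol readout of one line profile."""

    f_m: float
    f_c: float
    ratio: float
    peak_positions: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        if self.f_c <= 0:
            raise InvalidInputError("f_c must be positive to form a ratio")
        if self.ratio < 0:
            raise InvalidInputError("ratio must be >= 0")


@dataclass
class NuclearTranslocation:
    i_nuc: float
    i_cyto: float
    ratio: float
    mode: str = "mean"

    def __post_init__(self) -> None:
        if self.i_cyto <= 0:
            raise InvalidInputError("i_cyto must be positive to form a ratio")


@dataclass
class TirfTimecourse:
    """Baseline-subtracted masked-mean intensity time series.

    ``baseline_subtracted[0]`` is exactly 0 by construction (the t = 0
    mean is subtracted from every timepoint).
    """

    time_labels: np.ndarray  # minutes
    mean_intensities: np.ndarray
    baseline_subtracted: np.ndarray

    def __post_init__(self) -> None:
        if self.baseline_subtracted[0] != 0.0:
            raise InvalidInputError("baseline-subtracted series must start at exactly 0")


@dataclass
class Pip2Map:
    """Spatially resolved lipid concentration in mol%.

    ``spatial_average`` is the mean over valid masked pixels;
    ``n_clamped`` counts pixels whose ratio fell outside the calibration
    domain and was clamped; ``display_bounds`` are the recommended color
    scale for 3-D surface display.
    """

    concentration: np.ndarray
    mask: np.ndarray
    spatial_average: float
    n_clamped: int = 0
    display_bounds: tuple[float, float] = DISPLAY_BOUNDS_MOLPCT

    def __post_init__(self) -> None:
        valid = self.concentration[self.mask & np.isfinite(self.concentration)]
        if valid.size and np.any(valid < 0):
            raise InvalidInputError("concentrations must be >= 0 mol%")


# ---------------------------------------------------------------------------
# Membrane translocation (line profiles)
# ---------------------------------------------------------------------------

def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + y.size]
    return out


def membrane_ratio_from_profile(
    p: LineProfile, smoothing_window: int = 1
) -> MembraneTranslocation:
    """Membrane/cytosol ratio Fm/Fc from a two-peak line profile.

    After optional moving-average smoothing, the plasma-membrane peaks
    are the highest local maxima in the outer thirds of the profile span
    (one per side). Fm is the mean of the two peak intensities; Fc is the
    mean intensity strictly between the peaks, excluding a half-window
    buffer around each peak. Raises :class:`ProfileShapeError` when a
    membrane peak cannot be found on each side, signalling the caller to
    redraw the line.

    The ratio is invariant to multiplying the profile by a positive
    constant and to reversing the direction of the line.
    """
    if smoothing_window < 1:
        raise InvalidInputError("smoothing_window must be >= 1")
    y = _smooth(p.intensities, smoothing_window)
    n = y.size
    peaks, _ = find_peaks(y, plateau_size=1)
    third = n / 3.0
    left = [i for i in peaks if i < third]
    right = [i for i in peaks if i >= 2.0 * third]
    if not left or not right:
        raise ProfileShapeError(
            "could not find a membrane peak in each outer third of the profile; "
            "redraw the line across the whole cell (avoiding the nucleus)"
        )
    li = max(left, key=lambda i: (y[i], -i))
    ri = max(right, key=lambda i: (y[i], i))
    f_m = float((y[li] + y[ri]) / 2.0)
    buffer = max(1, smoothing_window // 2)
    lo, hi = li + buffer + 1, ri - buffer
    if hi <= lo:
        raise ProfileShapeError("membrane peaks leave no cytosolic span between them")
    f_c = float(np.mean(y[lo:hi]))
    if f_c <= 0:
        raise ProfileShapeError("cytosolic intensity is not positive; ratio undefined")
    return MembraneTranslocation(
        f_m=f_m,
        f_c=f_c,
        ratio=f_m / f_c,
        peak_positions=(float(p.positions[li]), float(p.positions[ri])),
    )


def sample_line_profile(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    n_samples: int = 200,
    pixel_size_um: float = 1.0,
) -> LineProfile:
    """Bilinear sample of an image along a line from ``start`` to ``end``.

    ``start``/``end`` are (row, col) pixel coordinates; positions are
    um along the line.
    """
    if n_samples < 10:
        raise InvalidInputError("need at least 10 samples along the line")
    r = np.linspace(start[0], end[0], n_samples)
    c = np.linspace(start[1], end[1], n_samples)
    from scipy.ndimage import map_coordinates

    vals = map_coordinates(np.asarray(image, dtype=float), [r, c], order=1)
    length = np.hypot(end[0] - start[0], end[1] - start[1]) * pixel_size_um
    pos = np.linspace(0.0, length, n_samples)
    return LineProfile(pos, vals)


# ---------------------------------------------------------------------------
# Nuclear translocation
# ---------------------------------------------------------------------------

def nuclear_ratio(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    cytoplasm_mask: np.ndarray,
    mode: str = "mean",
    min_pixels: int = 50,
) -> NuclearTranslocation:
    """Nucleus-to-cytoplasm intensity ratio Inuc/Icyto from masks.

    ``mode="mean"`` (default) uses mean intensities and is independent of
    compartment area; ``mode="total"`` uses integrated intensities.
    Masks must be disjoint and each cover at least ``min_pixels`` pixels.
    """
    img = np.asarray(image, dtype=float)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    cyt = np.asarray(cytoplasm_mask, dtype=bool)
    if img.shape != nuc.shape or img.shape != cyt.shape:
        raise InvalidInputError("image and masks must share a shape")
    if np.any(nuc & cyt):
        raise InvalidInputError("nucleus and cytoplasm masks must be disjoint")
    if nuc.sum() < min_pixels or cyt.sum() < min_pixels:
        raise InvalidInputError(f"each mask must cover at least {min_pixels} pixels")
    if mode == "mean":
        i_nuc, i_cyto = float(img[nuc].mean()), float(img[cyt].mean())
    elif mode == "total":
        i_nuc, i_cyto = float(img[nuc].sum()), float(img[cyt].sum())
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")
    return NuclearTranslocation(i_nuc=i_nuc, i_cyto=i_cyto, ratio=i_nuc / i_cyto, mode=mode)


def nuclear_ratio_from_lines(
    profiles: Sequence[LineProfile],
    nuclear_spans: Sequence[tuple[float, float]],
) -> NuclearTranslocation:
    """Inuc/Icyto from >= 5 cross-sectional lines with explicit nuclear spans.

    For each line, the nuclear segment is the samples inside the supplied
    (start, end) position span and the cytoplasmic segment is everything
    outside it; per-line means are averaged across lines before the ratio
    is formed. Line placement (over non-nuclear bright regions, etc.) is
    the caller's responsibility — spans are explicit coordinates.
    """
    if len(profiles) < 5:
        raise InvalidInputError("need at least 5 cross-sectional line profiles")
    if len(profiles) != len(nuclear_spans):
        raise InvalidInputError("one nuclear span per profile is required")
    nuc_means, cyt_means = [], []
    for prof, (a, b) in zip(profiles, nuclear_spans):
        inside = (prof.positions >= a) & (prof.positions <= b)
        if not inside.any() or inside.all():
            raise InvalidInputError("nuclear span must cover part, not all, of the line")
        nuc_means.append(prof.intensities[inside].mean())
        cyt_means.append(prof.intensities[~inside].mean())
    i_nuc = float(np.mean(nuc_means))
    i_cyto = float(np.mean(cyt_means))
    return NuclearTranslocation(i_nuc=i_nuc, i_cyto=i_cyto, ratio=i_nuc / i_cyto, mode="lines")


# ---------------------------------------------------------------------------
# TIRF membrane-recruitment time course
# ---------------------------------------------------------------------------

def tirf_timecourse(
    images_by_time: Mapping[float, np.ndarray],
    cell_mask: np.ndarray | None = None,
) -> TirfTimecourse:
    """Masked mean intensity per timepoint, baseline-subtracted at t = 0.

    ``images_by_time`` maps a time label (minutes) to a frame or small
    stack (averaged over its frames). A t = 0 entry must be present; its
    mean is subtracted from every timepoint so the series starts at
    exactly 0.
    """
    times = sorted(images_by_time)
    if 0 not in times and 0.0 not in times:
        raise InvalidInputError("a t = 0 baseline timepoint is required")
    means = []
    for t in times:
        img = np.asarray(images_by_time[t], dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=0)
        vals = img[np.asarray(cell_mask, dtype=bool)] if cell_mask is not None else img
        if vals.size == 0:
            raise InvalidInputError("cell mask selects no pixels")
        means.append(float(vals.mean()))
    means = np.asarray(means)
    baseline = means[times.index(0)] if 0 in times else means[times.index(0.0)]
    return TirfTimecourse(
        time_labels=np.asarray(times, dtype=float),
        mean_intensities=means,
        baseline_subtracted=means - baseline,
    )


def aggregate_timecourses(courses: Sequence[TirfTimecourse]) -> pd.DataFrame:
    """Mean +/- SD of baseline-subtracted series across cells."""
    if not courses:
        raise InvalidInputError("need at least one timecourse")
    ref = courses[0].time_labels
    for c in courses[1:]:
        if not np.array_equal(c.time_labels, ref):
            raise InvalidInputError("all timecourses must share the same time labels")
    mat = np.vstack([c.baseline_subtracted for c in courses])
    return pd.DataFrame(
        {
            "time_min": ref,
            "mean": mat.mean(axis=0),
            "sd": mat.std(axis=0, ddof=1) if len(courses) > 1 else np.zeros(ref.size),
            "n_cells": len(courses),
        }
    )


# ---------------------------------------------------------------------------
# Ratiometric lipid quantification
# ---------------------------------------------------------------------------

def _calibration_fn(calibration):
    """Accept a callable ratio->mol% or an (n, 2) table of (ratio, mol%).

    Returns (fn, domain): the mapping function and, for tables, the
    (lo, hi) ratio domain used for clamping (None for callables).
    """
    if callable(calibration):
        return calibration, None
    table = np.asarray(calibration, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise InvalidInputError("calibration table must be (n >= 2) x 2 of (ratio, mol%)")
    r, m = table[:, 0], table[:, 1]
    order = np.argsort(r)
    r, m = r[order], m[order]
    if not np.all(np.diff(r) > 0):
        raise InvalidInputError("calibration ratios must be strictly monotone")
    return (lambda x: np.interp(x, r, m)), (float(r[0]), float(r[-1]))


def pip2_concentration_map(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    calibration,
    mask: np.ndarray | None = None,
) -> Pip2Map:
    """Per-pixel lipid concentration (mol%) from a two-channel ratio image.

    The per-pixel ratio a/b is mapped through ``calibration`` — a callable
    ratio -> mol%, or an (n, 2) table interpolated piecewise-linearly.
    Denominator pixels below 1% of the masked median of b are excluded
    (division guard). Ratios outside a table calibration's domain are
    clamped to its edge, counted in ``n_clamped`` and reported via a
    warning. ``spatial_average`` is the mean mol% over the valid mask.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("channel images must share a shape")
    m = np.ones(a.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if m.shape != a.shape:
        raise InvalidInputError("mask must match the image shape")
    fn, domain = _calibration_fn(calibration)
    b_masked = b[m]
    if b_masked.size == 0:
        raise InvalidInputError("mask selects no pixels")
    floor = RATIO_FLOOR_FRACTION * np.median(b_masked)
    valid = m & (b > floor)
    ratio = np.full(a.shape, np.nan)
    ratio[valid] = a[valid] / b[valid]
    n_clamped = 0
    if domain is not None:
        lo, hi = domain
        clamped = valid & ((ratio < lo) | (ratio > hi))
        n_clamped = int(clamped.sum())
        if n_clamped:
            import warnings

            warnings.warn(
                f"{n_clamped} pixel ratio(s) outside the calibration domain were clamped",
                stacklevel=2,
            )
        ratio = np.clip(ratio, lo, hi)
    conc = np.full(a.shape, np.nan)
    conc[valid] = np.asarray(fn(ratio[valid]), dtype=float)
    avg = float(np.nanmean(conc[valid])) if valid.any() else float("nan")
    return Pip2Map(
        concentration=conc, mask=valid, spatial_average=avg, n_clamped=n_clamped
    )
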