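"""Spot detection, track linking and two-channel registration.

Single-molecule movies come in as image stacks (or pre-extracted
localization tables); this module turns them into trajectories in a
common coordinate frame:

* ``detect_spots`` — difference-of-Gaussians band-pass, thresholded local
  maxima, intensity-weighted sub-pixel centroid refinement;
* ``link_tracks`` — frame-to-frame optimal bipartite matching (minimum
  total squared displacement under a distance gate), with gap closing;
* ``estimate_registration`` / ``apply_registration`` — least-squares
  affine mapping of channel-2 coordinates into the channel-1 frame from
  fiducial pairs, as done with bead fields for chromatic correction.

All coordinates are continuous nanometres with the pixel-center
convention (pixel (i, j) center at ((j+0.5), (i+0.5)) * pixel_size) and
origin at the top-left image corner; every threshold is in nm, never in
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .errors import InvalidInputError

__all__ = [
    "AffineTransform",
    "detect_spots",
    "link_tracks",
    "estimate_registration",
    "apply_registration",
]

SPOT_COLUMNS = ["frame", "channel", "x_nm", "y_nm", "intensity"]
TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_nm", "y_nm", "channel"]

_BIG = 1e18  # cost standing in for "forbidden assignment"


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

@dataclass
class AffineTransform:
    """2-D affine map ``x -> linear @ x + offset`` (nm).

    ``rms_residual`` records the fiducial fit quality when the transform
    was estimated from bead pairs.
    """

    linear: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.linear)) <= 1e-6:
            raise InvalidInputError("affine linear part is (near-)singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.offset)


def estimate_registration(
    fiducial_pairs: Sequence[tuple[tuple[float, float], tuple[float, float]]],
) -> AffineTransform:
    """Least-squares affine transform taking channel-2 points onto channel 1.

    ``fiducial_pairs`` holds ((x1, y1), (x2, y2)) matched bead positions.
    Requires >= 3 non-collinear pairs; solves the normal equations of
    ``[x2 y2 1] @ M = [x1 y1]`` and records the RMS residual.
    """
    pairs = list(fiducial_pairs)
    if len(pairs) < 3:
        raise InvalidInputError("need at least 3 fiducial pairs")
    p1 = np.array([p[0] for p in pairs], dtype=float)
    p2 = np.array([p[1] for p in pairs], dtype=float)
    centered = p2 - p2.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(p2).max())) < 2:
        raise InvalidInputError("fiducial pairs are collinear; affine map is degenerate")
    design = np.column_stack([p2, np.ones(len(pairs))])
    coef, *_ = np.linalg.lstsq(design, p1, rcond=None)
    linear = coef[:2].T
    offset = coef[2]
    resid = design @ coef - p1
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform(linear, offset, rms_residual=rms)


def apply_registration(t: AffineTransform, data):
    """Map spots/tracks (DataFrame with x_nm/y_nm) or an (n, 2) array.

    Returns the same type; DataFrames are copied, gain transformed
    coordinates, and record the transform in ``df.attrs["registration"]``.
    """
    if isinstance(data, pd.DataFrame):
        out = data.copy()
        xy = t.apply(out[["x_nm", "y_nm"]].to_numpy())
        out[["x_nm", "y_nm"]] = xy
        out.attrs["registration"] = {
            "linear": t.linear.tolist(),
            "offset": t.offset.tolist(),
        }
        return out
    return t.apply(np.asarray(data, dtype=float))


# ---------------------------------------------------------------------------
# Spot detection
# ---------------------------------------------------------------------------

def _detect_in_frame(
    frame: np.ndarray,
    sigma_px: float,
    snr_threshold: float,
    pixel_size: float,
    frame_index: int,
    channel: str,
) -> list[dict]:
    dog = gaussian_filter(frame.astype(float), sigma_px) - gaussian_filter(
        frame.astype(float), 2.0 * sigma_px
    )
    med = np.median(dog)
    mad_sd = 1.4826 * np.median(np.abs(dog - med))
    if mad_sd == 0:
        mad_sd = dog.std() or 1e-12
    thr = med + snr_threshold * mad_sd
    # two spots closer than ~2 sigma are unresolvable at this PSF, so
    # candidate maxima nearer than that are shoulder artefacts of a peak
    peaks = peak_local_max(
        dog,
        min_distance=max(1, int(np.ceil(2.0 * sigma_px))),
        threshold_abs=thr,
        exclude_border=False,
    )
    # merge duplicates within one sigma, keeping the brighter peak
    kept: list[tuple[int, int]] = []
    order = np.argsort(-dog[peaks[:, 0], peaks[:, 1]]) if len(peaks) else []
    for idx in order:
        py, px = peaks[idx]
        if all((py - qy) ** 2 + (px - qx) ** 2 > sigma_px**2 for qy, qx in kept):
            kept.append((py, px))

    half = max(1, int(round(4.0 * sigma_px)))
    ny, nx = dog.shape
    out = []
    for py, px in kept:
        i0, i1 = max(0, py - half), min(ny, py + half + 1)
        j0, j1 = max(0, px - half), min(nx, px + half + 1)
        win = np.clip(dog[i0:i1, j0:j1], 0, None)
        total = win.sum()
        if total <= 0:
            continue
        ii, jj = np.mgrid[i0:i1, j0:j1]
        cy = float((win * ii).sum() / total)
        cx = float((win * jj).sum() / total)
        out.append(
            {
                "frame": frame_index,
                "channel": channel,
                "x_nm": (cx + 0.5) * pixel_size,
                "y_nm": (cy + 0.5) * pixel_size,
                "intensity": float(dog[py, px]),
            }
        )
    return out


def detect_spots(
    stack: np.ndarray,
    psf_sigma: float,
    snr_threshold: float,
    pixel_size: float,
    channel: str = "ch1",
) -> pd.DataFrame:
    """Detect diffraction-limited spots in an image stack.

    Each frame is band-passed with a difference of Gaussians at
    ``psf_sigma`` and ``2 * psf_sigma`` (nm, converted internally to
    pixels); local maxima above ``snr_threshold`` times the robust
    (MAD-based) background SD of the band-passed frame are kept, duplicate
    maxima within one sigma merged (brighter wins), and positions refined
    by the intensity-weighted centroid in a 4-sigma-radius window on the
    positive band-passed signal.

    Returns a localization table with columns
    ``frame, channel, x_nm, y_nm, intensity`` (coordinates in nm,
    pixel-center convention).
    """
    if psf_sigma <= 0:
        raise InvalidInputError("psf_sigma must be positive")
    if pixel_size <= 0:
        raise InvalidInputError("pixel_size must be positive")
    arr = np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InvalidInputError("stack must be a 2-D frame or a 3-D (t, y, x) array")
    sigma_px = psf_sigma / pixel_size
    rows: list[dict] = []
    for f in range(arr.shape[0]):
        rows.extend(_detect_in_frame(arr[f], sigma_px, snr_threshold, pixel_size, f, channel))
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def _match_frame(
    last_xy: np.ndarray,
    gates: np.ndarray,
    new_xy: np.ndarray,
    base_gate: float,
    gap_penalty: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Optimal assignment of active tracks to new spots.

    Minimises total squared displacement over admissible pairs
    (distance <= per-track gate). Leaving a track or spot unmatched
    costs a flat ``base_gate ** 2`` — deliberately independent of how
    stale a track is — while ``gap_penalty`` surcharges matches that
    resume across skipped frames. Together these make a track seen in
    the previous frame always outcompete a stale one for the same spot;
    otherwise a spurious track can survive indefinitely by time-sharing
    a single molecule's detections with the genuine track. Deterministic:
    scipy's Hungarian solver plus stable ordering.
    """
    nt, ns = len(last_xy), len(new_xy)
    if nt == 0 or ns == 0:
        return []
    d2 = np.sum((last_xy[:, None, :] - new_xy[None, :, :]) ** 2, axis=2)
    gate2 = gates[:, None] ** 2
    penalty = np.zeros((nt, 1)) if gap_penalty is None else gap_penalty[:, None]
    cost = np.where(d2 <= gate2, d2 + penalty, _BIG)
    alt = base_gate**2
    full = np.full((nt + ns, nt + ns), _BIG)
    full[:nt, :ns] = cost
    full[np.arange(nt), ns + np.arange(nt)] = alt  # track skips this frame
    full[nt + np.arange(ns), np.arange(ns)] = alt  # spot starts a new track
    full[nt:, ns:] = 0.0
    rows, cols = linear_sum_assignment(full)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < nt and c < ns and d2[r, c] <= gate2[r, 0]
    ]


def _interp_positions(points: list[tuple[int, float, float]]) -> dict[int, tuple[float, float]]:
    """Frame -> position over a track's span, linearly interpolated in gaps."""
    out: dict[int, tuple[float, float]] = {points[0][0]: points[0][1:]}
    for (f0, x0, y0), (f1, x1, y1) in zip(points, points[1:]):
        for g in range(f0 + 1, f1):
            w = (g - f0) / (f1 - f0)
            out[g] = (x0 + w * (x1 - x0), y0 + w * (y1 - y0))
        out[f1] = (x1, y1)
    return out


def _suppress_phantom_tracks(tracks: list[dict], radius: float) -> list[dict]:
    """Drop tracks that shadow another track within ``radius`` nm.

    For each coexisting pair whose temporal overlap covers at least half
    of the shorter track's span, the median inter-track distance over the
    overlap decides: below ``radius`` the track with fewer real
    detections (ties: the shorter, then the later-born) is discarded.
    """
    spans = [(t["points"][0][0], t["points"][-1][0]) for t in tracks]
    pos = [_interp_positions(t["points"]) for t in tracks]
    # rank: more detections first, then earlier birth
    order = sorted(
        range(len(tracks)),
        key=lambda i: (-len(tracks[i]["points"]), spans[i][0], i),
    )
    dropped: set[int] = set()
    for rank, i in enumerate(order):
        if i in dropped:
            continue
        for j in order[rank + 1 :]:
            if j in dropped:
                continue
            lo = max(spans[i][0], spans[j][0])
            hi = min(spans[i][1], spans[j][1])
            if hi < lo:
                continue
            span_j = spans[j][1] - spans[j][0] + 1
            if (hi - lo + 1) < 0.5 * span_j:
                continue
            d = [
                np.hypot(pos[i][f][0] - pos[j][f][0], pos[i][f][1] - pos[j][f][1])
                for f in range(lo, hi + 1)
            ]
            if np.median(d) < radius:
                dropped.add(j)
    return [t for k, t in enumerate(tracks) if k not in dropped]


def link_tracks(
    spots: pd.DataFrame,
    max_displacement: float,
    max_gap: int = 1,
    min_track_length: int = 4,
    frame_interval: float = 1.0,
    interpolate_gaps: bool = False,
    dedupe_radius: float | None = None,
) -> pd.DataFrame:
    """Link a localization table into trajectories.

    Consecutive-frame assignments minimise the total squared displacement
    among pairs closer than ``max_displacement`` (optimal bipartite
    matching on the gated cost matrix); unmatched spots seed new tracks.
    A track missing from up to ``max_gap`` frames may be resumed, with
    the distance gate scaled proportionally to the number of elapsed
    frames. Tracks shorter than ``min_track_length`` localizations are
    discarded. With ``interpolate_gaps`` the skipped frames of a closed
    gap are filled by linear interpolation between the bracketing
    detections, so downstream frame-run analyses (e.g. colocalization
    event calling) do not split an event at a single missed detection.

    ``dedupe_radius`` (nm) enables phantom-track suppression: when two
    tracks coexist and their interpolated positions stay within this
    radius (median over the overlap) for at least half of the shorter
    track's life, the one with fewer real detections is dropped. Gap
    closing can otherwise let a spurious birth "time-share" a single
    molecule's detections with the genuine track indefinitely. Use a
    radius well above the localization error but below typical
    inter-molecule distances (e.g. 2 pixels); leave ``None`` for data
    where distinct molecules may legitimately stay that close.

    Returns a track table with columns
    ``track_id, frame, time_s, x_nm, y_nm, channel``, deterministic and
    invariant to the ordering of spots within a frame.
    """
    if max_displacement <= 0:
        raise InvalidInputError("max_displacement must be positive")
    if max_gap < 0 or min_track_length < 1:
        raise InvalidInputError("max_gap must be >= 0 and min_track_length >= 1")
    if frame_interval <= 0:
        raise InvalidInputError("frame_interval must be positive")
    required = {"frame", "x_nm", "y_nm"}
    if not required.issubset(spots.columns):
        raise InvalidInputError(f"spots table needs columns {sorted(required)}")
    if len(spots) == 0:
        return pd.DataFrame(columns=TRACK_COLUMNS)

    # canonical order makes the result independent of input row order
    df = spots.sort_values(["frame", "x_nm", "y_nm"], kind="mergesort").reset_index(drop=True)
    channel = df["channel"].iloc[0] if "channel" in df.columns else "ch1"

    tracks: list[dict] = []  # {"last_frame", "x", "y", "points": [(f, x, y)]}
    for f in sorted(df["frame"].unique()):
        sub = df[df["frame"] == f]
        new_xy = sub[["x_nm", "y_nm"]].to_numpy(dtype=float)
        active_idx = [
            i for i, t in enumerate(tracks) if 1 <= f - t["last_frame"] <= max_gap + 1
        ]
        matched_spots: set[int] = set()
        if active_idx:
            last_xy = np.array([[tracks[i]["x"], tracks[i]["y"]] for i in active_idx])
            gaps = np.array([f - tracks[i]["last_frame"] for i in active_idx])
            gates = max_displacement * gaps.astype(float)
            penalty = (gaps - 1).astype(float) * max_displacement**2
            for r, c in _match_frame(last_xy, gates, new_xy, max_displacement,
                                     gap_penalty=penalty):
                t = tracks[active_idx[r]]
                t["points"].append((int(f), new_xy[c, 0], new_xy[c, 1]))
                t["last_frame"], t["x"], t["y"] = int(f), new_xy[c, 0], new_xy[c, 1]
                matched_spots.add(c)
        for c in range(len(new_xy)):
            if c not in matched_spots:
                tracks.append(
                    {
                        "last_frame": int(f),
                        "x": new_xy[c, 0],
                        "y": new_xy[c, 1],
                        "points": [(int(f), new_xy[c, 0], new_xy[c, 1])],
                    }
                )

    if dedupe_radius is not None:
        tracks = _suppress_phantom_tracks(tracks, dedupe_radius)

    rows = []
    tid = 0
    for t in tracks:
        if len(t["points"]) < min_track_length:
            continue
        points = t["points"]
        if interpolate_gaps:
            filled: list[tuple[int, float, float]] = [points[0]]
            for (f0, x0, y0), (f1, x1, y1) in zip(points, points[1:]):
                for g in range(f0 + 1, f1):
                    w = (g - f0) / (f1 - f0)
                    filled.append((g, x0 + w * (x1 - x0), y0 + w * (y1 - y0)))
                filled.append((f1, x1, y1))
            points = filled
        for f, x, y in points:
            rows.append(
                {
                    "track_id": tid,
                    "frame": f,
                    "time_s": f * frame_interval,
                    "x_nm": x,
                    "y_nm": y,
                    "channel": channel,
                }
            )
        tid += 1
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)
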