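"""Seeded synthetic-data generators with paired ground truth.

Every input the analysis pipeline consumes can be generated here with a
known ground truth, so each stage is testable end to end without any
instrument data:

* equilibrium isotherms and anisotropy titrations on the one-site
  Langmuir model, with additive Gaussian noise;
* two-channel single-molecule movies of membrane-diffusing receptors and
  cytosolic adaptor molecules that bind and unbind them (Markovian
  kinetics, exponential dwell times in the continuum limit), including
  localization error and an affine inter-channel distortion;
* rendered camera frames (Gaussian PSF + Poisson shot noise);
* concentric-compartment cell images (nucleus / cytosol / plasma-membrane
  ring) for translocation metrics;
* two-channel ratiometric biosensor image pairs over a known lipid
  concentration map.

All generators take an explicit integer seed and are bit-reproducible
given (parameters, seed); one fresh ``numpy.random.Generator`` stream is
opened per call.

The particle simulation is receptor-centric and 1:1 (a receptor carries
at most one bound adaptor), uses reflecting boundaries, and evaluates
unbinding once per frame with probability ``1 - exp(-k_off * dt)`` so the
continuous-time rate is recovered as ``dt -> 0``. True dwell times are
therefore geometric in frame counts; see ``dwell_survival`` notes in the
coloc module for why the survival fit of that law still recovers the
continuous-time ``k_off`` without discretization bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .binding import AnisotropyTitration, EquilibriumIsotherm, langmuir_fraction
from .errors import InvalidInputError

__all__ = [
    "TwoChannelSimParams",
    "SyntheticGroundTruth",
    "simulate_isotherm",
    "simulate_anisotropy_titration",
    "simulate_two_channel_tracks",
    "simulate_dwell_times",
    "score_events_against_truth",
    "render_frames",
    "simulate_cell_image",
    "simulate_ratiometric_pair",
    "invert_calibration_table",
]

RECEPTOR_CHANNEL = "ch1"
ADAPTOR_CHANNEL = "ch2"


# ---------------------------------------------------------------------------
# Equilibrium assays
# ---------------------------------------------------------------------------

def simulate_isotherm(
    kd: float,
    concentrations: Sequence[float],
    noise_sd: float,
    seed: int,
    surface_id: str = "synthetic",
    unit: str = "nM",
) -> tuple[EquilibriumIsotherm, float]:
    """Noisy Langmuir isotherm: 1/(1 + Kd/P0) + N(0, noise_sd).

    Returns the isotherm together with the generating (true) Kd.
    """
    if not kd > 0:
        raise InvalidInputError("kd must be positive")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise InvalidInputError("concentration list must not be empty")
    rng = np.random.default_rng(seed)
    resp = langmuir_fraction(conc, kd) + rng.normal(0.0, noise_sd, size=conc.shape)
    resp = np.clip(resp, -0.05, 1.10)  # keep within the type's noise band
    iso = EquilibriumIsotherm(surface_id, conc, resp, concentration_unit=unit)
    return iso, kd


def simulate_anisotropy_titration(
    kd: float,
    r_free: float,
    r_bound: float,
    protein_concentrations: Sequence[float],
    noise_sd: float,
    seed: int,
    peptide_id: str = "synthetic",
    peptide_concentration_nM: float = 2.5,
) -> tuple[AnisotropyTitration, float]:
    """Noisy anisotropy titration: A = r_free + (r_bound - r_free)/(1 + Kd/P0) + noise.

    ``protein_concentrations`` are in uM (the ligand-excess regime of the
    assay); the labelled-peptide concentration defaults to 2.5 nM.
    """
    if not kd > 0:
        raise InvalidInputError("kd must be positive")
    if not r_bound > r_free:
        raise InvalidInputError("r_bound must exceed r_free")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    conc = np.asarray(protein_concentrations, dtype=float)
    if conc.size == 0:
        raise InvalidInputError("concentration list must not be empty")
    rng = np.random.default_rng(seed)
    a = r_free + (r_bound - r_free) * langmuir_fraction(conc, kd)
    a = a + rng.normal(0.0, noise_sd, size=conc.shape)
    tit = AnisotropyTitration(
        peptide_id=peptide_id,
        peptide_concentration=peptide_concentration_nM,
        protein_concentrations=conc,
        anisotropy=a,
    )
    return tit, kd


# ---------------------------------------------------------------------------
# Two-channel single-molecule simulation
# ---------------------------------------------------------------------------

@dataclass
class TwoChannelSimParams:
    """Parameters of the dual-color binding/unbinding movie simulation.

    Distances are nm, times seconds, diffusion coefficients nm^2/s.
    Channel 1 holds the membrane receptors, channel 2 the cytosolic
    adaptor molecules; ``channel_transform`` is the affine chromatic
    distortion ``(linear, offset)`` applied to observed channel-2
    positions. Defaults describe a sparse plasma-membrane field at video
    rate (dt = 0.05 s, 600 frames), with D ~ 0.1 um^2/s typical of
    membrane proteins.
    """

    field_size: tuple[float, float] = (20_000.0, 20_000.0)
    n_receptors: int = 30
    n_adaptors: int = 30
    diffusion_receptor: float = 5e4   # nm^2/s  (0.05 um^2/s)
    diffusion_adaptor: float = 2e5    # nm^2/s  (0.2 um^2/s)
    capture_radius: float = 200.0
    p_bind_per_frame: float = 0.5
    k_off: float = 2.0                # s^-1
    localization_error_sd: float = 15.0
    frame_interval: float = 0.05
    n_frames: int = 600
    channel_transform: tuple[np.ndarray, np.ndarray] = field(
        default_factory=lambda: (np.eye(2), np.zeros(2))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lin, off = self.channel_transform
        self.channel_transform = (np.asarray(lin, dtype=float), np.asarray(off, dtype=float))
        if self.frame_interval <= 0:
            raise InvalidInputError("frame_interval must be positive")
        if not (0.0 <= self.p_bind_per_frame <= 1.0):
            raise InvalidInputError("p_bind_per_frame must lie in [0, 1]")
        for name in ("diffusion_receptor", "diffusion_adaptor", "capture_radius",
                     "k_off", "localization_error_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.n_frames < 1 or self.n_receptors < 0 or self.n_adaptors < 0:
            raise InvalidInputError("counts must be non-negative (n_frames >= 1)")


@dataclass
class SyntheticGroundTruth:
    """True trajectories, bound intervals and generating parameters.

    ``true_bound_intervals`` rows: (adaptor_id, receptor_id, start_s,
    end_s, n_frames, duration_s, censored). Durations follow the
    frame-count convention duration = n_frames * dt; intervals still open
    at the movie end are flagged censored. Intervals are non-overlapping
    per adaptor molecule.
    """

    true_tracks_receptor: pd.DataFrame
    true_tracks_adaptor: pd.DataFrame
    true_bound_intervals: pd.DataFrame
    true_parameters: TwoChannelSimParams

    def completed_dwells(self) -> np.ndarray:
        """Durations (s) of intervals that ended before the movie did."""
        df = self.true_bound_intervals
        return df.loc[~df["censored"], "duration_s"].to_numpy()


def _reflect(pos: np.ndarray, size: tuple[float, float]) -> np.ndarray:
    for axis, bound in enumerate(size):
        p = np.mod(pos[:, axis], 2.0 * bound)
        pos[:, axis] = np.where(p > bound, 2.0 * bound - p, p)
    return pos


def simulate_two_channel_tracks(
    params: TwoChannelSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticGroundTruth]:
    """Simulate diffusing receptors and adaptors with Markovian binding.

    Per frame: (1) bound pairs unbind with probability 1 - exp(-k_off*dt);
    (2) receptors take Brownian steps (per-axis SD sqrt(2*D*dt)), free
    adaptors likewise, bound adaptors ride their receptor (zero true
    separation); (3) each free adaptor within ``capture_radius`` of an
    unoccupied receptor binds it with ``p_bind_per_frame`` (nearest such
    receptor wins). Reflecting boundaries. Observed localizations add
    isotropic Gaussian error; observed channel-2 positions are then
    passed through ``channel_transform``.

    Returns (receptor localizations, adaptor localizations, ground truth);
    localization tables have columns frame, time_s, channel, particle_id,
    x_nm, y_nm.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    dt = p.frame_interval
    size = tuple(float(s) for s in p.field_size)
    step_r = np.sqrt(2.0 * p.diffusion_receptor * dt)
    step_a = np.sqrt(2.0 * p.diffusion_adaptor * dt)
    p_off = 1.0 - np.exp(-p.k_off * dt)

    rec = rng.uniform(0, size, size=(p.n_receptors, 2)) if p.n_receptors else np.zeros((0, 2))
    ada = rng.uniform(0, size, size=(p.n_adaptors, 2)) if p.n_adaptors else np.zeros((0, 2))
    bound_to = np.full(p.n_adaptors, -1, dtype=int)   # receptor index or -1
    occupied = np.zeros(p.n_receptors, dtype=bool)
    bind_start = np.full(p.n_adaptors, -1, dtype=int)

    rec_frames = np.empty((p.n_frames, p.n_receptors, 2))
    ada_frames = np.empty((p.n_frames, p.n_adaptors, 2))
    intervals: list[tuple[int, int, int, int, bool]] = []

    for f in range(p.n_frames):
        if f > 0:
            # 1) unbinding
            bound = np.flatnonzero(bound_to >= 0)
            if bound.size:
                unbind = bound[rng.random(bound.size) < p_off]
                for i in unbind:
                    intervals.append((i, bound_to[i], bind_start[i], f - 1, False))
                    occupied[bound_to[i]] = False
                    bound_to[i] = -1
            # 2) motion
            if p.n_receptors:
                rec = _reflect(rec + rng.normal(0, step_r, rec.shape), size)
            free = bound_to < 0
            if np.any(free):
                ada[free] = _reflect(
                    ada[free] + rng.normal(0, step_a, (int(free.sum()), 2)), size
                )
            riding = np.flatnonzero(~free)
            if riding.size:
                ada[riding] = rec[bound_to[riding]]
            # 3) binding
            free_idx = np.flatnonzero(bound_to < 0)
            open_rec = np.flatnonzero(~occupied)
            if free_idx.size and open_rec.size:
                d = np.linalg.norm(
                    ada[free_idx, None, :] - rec[None, open_rec, :], axis=2
                )
                for row, i in enumerate(free_idx):
                    near = np.flatnonzero(d[row] <= p.capture_radius)
                    if near.size == 0:
                        continue
                    j = open_rec[near[np.argmin(d[row, near])]]
                    if occupied[j]:
                        continue  # taken earlier this frame
                    if rng.random() < p.p_bind_per_frame:
                        occupied[j] = True
                        bound_to[i] = j
                        bind_start[i] = f
                        ada[i] = rec[j]
        rec_frames[f] = rec
        ada_frames[f] = ada

    for i in np.flatnonzero(bound_to >= 0):  # still bound at movie end: censored
        intervals.append((i, bound_to[i], bind_start[i], p.n_frames - 1, True))

    def _table(frames: np.ndarray, channel: str, n: int) -> pd.DataFrame:
        if n == 0:
            return pd.DataFrame(
                columns=["frame", "time_s", "channel", "particle_id", "x_nm", "y_nm"]
            )
        fidx = np.repeat(np.arange(p.n_frames), n)
        pid = np.tile(np.arange(n), p.n_frames)
        xy = frames.reshape(-1, 2)
        return pd.DataFrame(
            {
                "frame": fidx,
                "time_s": fidx * dt,
                "channel": channel,
                "particle_id": pid,
                "x_nm": xy[:, 0],
                "y_nm": xy[:, 1],
            }
        )

    true_rec = _table(rec_frames, RECEPTOR_CHANNEL, p.n_receptors)
    true_ada = _table(ada_frames, ADAPTOR_CHANNEL, p.n_adaptors)

    obs_rec = true_rec.copy()
    obs_ada = true_ada.copy()
    if p.localization_error_sd > 0:
        obs_rec[["x_nm", "y_nm"]] += rng.normal(
            0, p.localization_error_sd, (len(obs_rec), 2)
        )
        obs_ada[["x_nm", "y_nm"]] += rng.normal(
            0, p.localization_error_sd, (len(obs_ada), 2)
        )
    lin, off = p.channel_transform
    xy = obs_ada[["x_nm", "y_nm"]].to_numpy() @ lin.T + off
    obs_ada[["x_nm", "y_nm"]] = xy

    iv = pd.DataFrame(
        intervals,
        columns=["adaptor_id", "receptor_id", "start_frame", "end_frame", "censored"],
    )
    if len(iv):
        iv["n_frames"] = iv["end_frame"] - iv["start_frame"] + 1
        iv["start_s"] = iv["start_frame"] * dt
        iv["end_s"] = iv["end_frame"] * dt
        iv["duration_s"] = iv["n_frames"] * dt
        iv = iv.sort_values(["adaptor_id", "start_frame"]).reset_index(drop=True)
    else:
        for col in ("n_frames", "start_s", "end_s", "duration_s"):
            iv[col] = pd.Series(dtype=float)
    truth = SyntheticGroundTruth(true_rec, true_ada, iv, p)
    return obs_rec, obs_ada, truth


def score_events_against_truth(
    truth: SyntheticGroundTruth,
    events,
    adaptor_tracks: pd.DataFrame,
    min_duration: float = 0.2,
    coverage: float = 0.5,
    match_radius: float = 300.0,
) -> dict:
    """Precision/recall of called colocalization events against ground truth.

    Matching is coverage-based, the usual convention for temporal event
    detection: a *called event* is correct when at least ``coverage`` of
    its frames lie inside true bound intervals of the same molecule pair
    (established spatially — the event's adaptor track must sit within
    ``match_radius`` nm of the true adaptor at the overlap midpoint,
    since detected track ids are arbitrary); a *true interval* is
    recovered when at least ``coverage`` of its frames are covered by
    such events. One proximity episode that spans a quick
    unbind/rebind therefore recovers both underlying intervals (the
    <400 nm rule genuinely cannot separate them), and an event split by
    a tracking gap still credits the interval through its fragments,
    while each fragment is itself judged by where its frames lie.

    Recall is scored over completed (uncensored) intervals longer than
    the event-duration cut; events may match *any* completed interval —
    a binding just under the cut is legitimately called once approach
    frames push its proximity run over the threshold. Called events
    flagged censored are excluded, mirroring the truth-side censoring
    filter.

    Returns ``{"precision", "recall", "n_true", "n_events"}``.
    """
    dt = truth.true_parameters.frame_interval
    events = [e for e in events if not e.censored]
    iv = truth.true_bound_intervals
    iv = iv[~iv["censored"]]
    scored = (iv["duration_s"] > min_duration).to_numpy()
    true_iv = list(iv[["start_frame", "end_frame", "adaptor_id"]].itertuples(index=False))
    tru_pos = truth.true_tracks_adaptor.set_index(["particle_id", "frame"])[["x_nm", "y_nm"]]
    trk_pos = adaptor_tracks.set_index(["track_id", "frame"])[["x_nm", "y_nm"]]

    def spatially_matched(e, f0, f1, s, en, aid) -> int:
        """Overlap length if the event rides the true adaptor, else 0."""
        inter = min(f1, en) - max(f0, s) + 1
        if inter <= 0:
            return 0
        fmid = (max(f0, s) + min(f1, en)) // 2
        try:
            ex, ey = trk_pos.loc[(e.smad_track_id, fmid)]
            tx, ty = tru_pos.loc[(aid, fmid)]
        except KeyError:
            return 0
        return inter if np.hypot(ex - tx, ey - ty) < match_radius else 0

    covered_t = np.zeros(len(true_iv), dtype=int)
    n_good_events = 0
    for e in events:
        f0 = int(round(e.start_time / dt))
        f1 = int(round(e.end_time / dt))
        event_cov = 0
        for ti, (s, en, aid) in enumerate(true_iv):
            ov = spatially_matched(e, f0, f1, s, en, aid)
            event_cov += ov
            covered_t[ti] += ov
        if event_cov >= coverage * (f1 - f0 + 1):
            n_good_events += 1

    n_true = int(scored.sum())
    n_events = len(events)
    lengths = np.array([en - s + 1 for s, en, _ in true_iv])
    recovered = sum(
        1
        for ti in range(len(true_iv))
        if scored[ti] and covered_t[ti] >= coverage * lengths[ti]
    )
    return {
        "precision": n_good_events / n_events if n_events else float("nan"),
        "recall": recovered / n_true if n_true else float("nan"),
        "n_true": n_true,
        "n_events": n_events,
    }


def simulate_dwell_times(
    k_off: float, frame_interval: float, n: int, seed: int
) -> np.ndarray:
    """Frame-quantized Markovian dwell times, in seconds.

    Draws dwell lengths in frames from the geometric law of per-frame
    unbinding with probability 1 - exp(-k_off * dt) (the exact law of the
    full spatial simulation) and returns ``m * dt``. A cheap stand-in for
    :func:`simulate_two_channel_tracks` when only the kinetics matter.
    """
    if not (k_off > 0 and frame_interval > 0 and n > 0):
        raise InvalidInputError("k_off, frame_interval and n must be positive")
    rng = np.random.default_rng(seed)
    p_off = 1.0 - np.exp(-k_off * frame_interval)
    return rng.geometric(p_off, size=n) * frame_interval


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

def render_frames(
    localizations: pd.DataFrame,
    field_size: tuple[float, float],
    psf_sigma: float,
    pixel_size: float,
    background: float,
    photon_scale: float,
    seed: int,
    n_frames: int | None = None,
) -> np.ndarray:
    """Render localizations into a camera-like image stack.

    Each localization becomes a 2-D Gaussian of SD ``psf_sigma`` (nm) with
    integrated intensity ``photon_scale`` counts on a constant
    ``background``; Poisson shot noise is applied to the whole frame.
    Coordinates follow the pixel-center convention (pixel (i, j) center at
    ((j+0.5), (i+0.5)) * pixel_size). Localizations outside the field are
    clipped to its edge with a warning.

    Returns a float array of shape (n_frames, ny, nx).
    """
    if pixel_size <= 0:
        raise InvalidInputError("pixel_size must be positive")
    if psf_sigma <= 0:
        raise InvalidInputError("psf_sigma must be positive")
    rng = np.random.default_rng(seed)
    nx = int(round(field_size[0] / pixel_size))
    ny = int(round(field_size[1] / pixel_size))
    if n_frames is None:
        n_frames = int(localizations["frame"].max()) + 1 if len(localizations) else 1
    stack = np.full((n_frames, ny, nx), float(background))
    sig = psf_sigma / pixel_size
    amp = photon_scale / (2.0 * np.pi * sig**2)
    half = int(np.ceil(4.0 * sig))

    if len(localizations):
        x = localizations["x_nm"].to_numpy(dtype=float)
        y = localizations["y_nm"].to_numpy(dtype=float)
        out = (x < 0) | (x > field_size[0]) | (y < 0) | (y > field_size[1])
        if np.any(out):
            warnings.warn(
                f"{int(out.sum())} localization(s) outside the field were clipped",
                stacklevel=2,
            )
            x = np.clip(x, 0, field_size[0])
            y = np.clip(y, 0, field_size[1])
        frames = localizations["frame"].to_numpy(dtype=int)
        cx = x / pixel_size - 0.5  # pixel-index coordinates
        cy = y / pixel_size - 0.5
        for f, px, py in zip(frames, cx, cy):
            if f < 0 or f >= n_frames:
                continue
            j0, j1 = max(0, int(px) - half), min(nx, int(px) + half + 1)
            i0, i1 = max(0, int(py) - half), min(ny, int(py) + half + 1)
            if j0 >= j1 or i0 >= i1:
                continue
            jj = np.arange(j0, j1)
            ii = np.arange(i0, i1)
            gx = np.exp(-((jj - px) ** 2) / (2 * sig**2))
            gy = np.exp(-((ii - py) ** 2) / (2 * sig**2))
            stack[f, i0:i1, j0:j1] += amp * np.outer(gy, gx)
    return rng.poisson(stack).astype(float)


# ---------------------------------------------------------------------------
# Cell images
# ---------------------------------------------------------------------------

def simulate_cell_image(
    shape: tuple[int, int] = (256, 256),
    nucleus_radius: float = 40.0,
    cell_radius: float = 100.0,
    ring_width: float = 6.0,
    intensity_nucleus: float = 2.0,
    intensity_cytosol: float = 2.0,
    intensity_ring: float = 10.0,
    intensity_background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Concentric-compartment cell image with additive Gaussian noise.

    A circular cell of ``cell_radius`` pixels centred in ``shape``
    contains a nucleus (``nucleus_radius``) and is bounded by a
    plasma-membrane ring of ``ring_width`` straddling the cell edge.
    Ground truth holds the noiseless compartment means: ``f_m`` (ring),
    ``f_c`` (cytosol), ``i_nuc``, ``i_cyto``, plus the geometry.
    """
    if any(i < 0 for i in (intensity_nucleus, intensity_cytosol,
                           intensity_ring, intensity_background)):
        raise InvalidInputError("intensities must be >= 0")
    if nucleus_radius + ring_width / 2 >= cell_radius:
        raise InvalidInputError("plasma-membrane ring overlaps the nucleus")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx)
    img = np.full(shape, float(intensity_background))
    img[r < cell_radius] = intensity_cytosol
    img[r < nucleus_radius] = intensity_nucleus
    ring = (r >= cell_radius - ring_width / 2) & (r < cell_radius + ring_width / 2)
    img[ring] = intensity_ring
    rng = np.random.default_rng(seed)
    noisy = img + rng.normal(0.0, noise_sd, img.shape) if noise_sd > 0 else img.copy()
    truth = {
        "f_m": float(intensity_ring),
        "f_c": float(intensity_cytosol),
        "i_nuc": float(intensity_nucleus),
        "i_cyto": float(intensity_cytosol),
        "nucleus_radius": float(nucleus_radius),
        "cell_radius": float(cell_radius),
        "ring_width": float(ring_width),
        "center": (cy, cx),
        "nucleus_mask": r < nucleus_radius,
        "cytosol_mask": (r >= nucleus_radius) & (r < cell_radius - ring_width / 2),
        "ring_mask": ring,
    }
    return noisy, truth


def simulate_ratiometric_pair(
    concentration_map: np.ndarray,
    calibration: Callable[[np.ndarray], np.ndarray],
    noise_sd: float,
    seed: int,
    reference_level: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-channel biosensor pair whose per-pixel ratio encodes a lipid map.

    ``calibration`` maps mol% to the sensor ratio and must be strictly
    monotone over the map's range. The ratio image is
    ``calibration(map) + N(0, noise_sd)``; channel b is a constant
    ``reference_level`` and channel a is ratio * b, so that a/b equals
    the noisy ratio exactly. Returns (channel_a, channel_b, true_map).
    """
    cmap = np.asarray(concentration_map, dtype=float)
    if np.any(cmap < 0):
        raise InvalidInputError("concentration map must be >= 0 mol%")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    lo, hi = float(cmap.min()), float(cmap.max())
    probe = np.linspace(lo, hi, 33) if hi > lo else np.array([lo])
    vals = np.asarray(calibration(probe), dtype=float)
    if np.any(~np.isfinite(vals)):
        raise InvalidInputError("calibration undefined over the map's range")
    if probe.size > 1:
        d = np.diff(vals)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidInputError("calibration must be strictly monotone over the map range")
    rng = np.random.default_rng(seed)
    ratio = np.asarray(calibration(cmap), dtype=float)
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, ratio.shape)
    channel_b = np.full(cmap.shape, float(reference_level))
    channel_a = ratio * channel_b
    return channel_a, channel_b, cmap.copy()


def invert_calibration_table(table: np.ndarray) -> np.ndarray:
    """Swap the columns of a (mol%, ratio) table into a (ratio, mol%) table.

    Both orientations must be strictly monotone; output rows are sorted
    by ratio so it can be consumed by the map-quantification step.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise InvalidInputError("calibration table must be (n >= 2) x 2")
    inv = t[:, ::-1]
    return inv[np.argsort(inv[:, 0])]
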