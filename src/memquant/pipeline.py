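"""End-to-end synthetic-movie pipeline: render -> detect -> link -> register -> coloc.

Glue that chains the library stages on a simulated dual-color movie and
scores the result against the generator's ground truth. Used by the
test-suite and the reproduction script; the CLI exposes the same stages
individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coloc, synthetic, tracking

__all__ = ["EndToEndResult", "run_movie_pipeline"]

# rendering defaults: SNR = peak amplitude / sqrt(background) = 10
PSF_SIGMA_NM = 130.0
PIXEL_SIZE_NM = 100.0
BACKGROUND = 100.0
SNR = 10.0
RENDER_CHUNK = 200


@dataclass
class EndToEndResult:
    survival_fit: coloc.SurvivalFit
    event_scores: dict
    detection_recall: float
    localization_rmse_nm: float
    n_events: int
    events: list


def _detect_channel(
    locs: pd.DataFrame,
    params: synthetic.TwoChannelSimParams,
    channel: str,
    seed: int,
    snr_threshold: float,
) -> pd.DataFrame:
    """Render a localization table chunk-wise and detect spots."""
    photon = SNR * np.sqrt(BACKGROUND) * 2 * np.pi * (PSF_SIGMA_NM / PIXEL_SIZE_NM) ** 2
    out = []
    for f0 in range(0, params.n_frames, RENDER_CHUNK):
        n = min(RENDER_CHUNK, params.n_frames - f0)
        sub = locs[(locs["frame"] >= f0) & (locs["frame"] < f0 + n)].copy()
        sub["frame"] -= f0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # edge clipping of transformed spots
            stack = synthetic.render_frames(
                sub, params.field_size, PSF_SIGMA_NM, PIXEL_SIZE_NM,
                BACKGROUND, photon, seed=seed + f0, n_frames=n,
            )
        sp = tracking.detect_spots(stack, PSF_SIGMA_NM, snr_threshold, PIXEL_SIZE_NM,
                                   channel=channel)
        sp["frame"] += f0
        out.append(sp)
    return pd.concat(out, ignore_index=True)


def _detection_metrics(
    spots: pd.DataFrame, truth_locs: pd.DataFrame, radius_nm: float = 200.0
) -> tuple[float, float]:
    """(recall, localization RMSE) of detections against true positions."""
    hits = 0
    total = 0
    errs = []
    by_frame = {f: g for f, g in spots.groupby("frame")}
    for f, grp in truth_locs.groupby("frame"):
        det = by_frame.get(f)
        total += len(grp)
        if det is None or not len(det):
            continue
        dx = grp["x_nm"].to_numpy()[:, None] - det["x_nm"].to_numpy()[None, :]
        dy = grp["y_nm"].to_numpy()[:, None] - det["y_nm"].to_numpy()[None, :]
        d = np.hypot(dx, dy).min(axis=1)
        ok = d < radius_nm
        hits += int(ok.sum())
        errs.extend(d[ok])
    recall = hits / total if total else float("nan")
    rmse = float(np.sqrt(np.mean(np.square(errs)))) if errs else float("nan")
    return recall, rmse


def run_movie_pipeline(
    params: synthetic.TwoChannelSimParams,
    cfg: coloc.ColocConfig,
    n_fiducials: int = 20,
    fiducial_jitter_nm: float = 5.0,
    snr_threshold: float = 5.0,
    max_gap: int = 2,
    min_track_length: int = 4,
    registration_seed: int = 99,
) -> EndToEndResult:
    """Run the full chain on one simulated movie and score it.

    Simulates the movie, renders and detects both channels, estimates the
    inter-channel affine transform from a simulated fiducial-bead field
    passed through the same chromatic distortion (with localization
    jitter), registers channel 2 onto channel 1, links both channels
    (closing gaps by interpolation so single missed frames do not split
    events), calls colocalization events and fits the dwell survival
    curve.
    """
    rec, ada, truth = synthetic.simulate_two_channel_tracks(params)
    lin, off = params.channel_transform

    rng = np.random.default_rng(registration_seed)
    margin = 0.05 * min(params.field_size)
    beads = rng.uniform(margin, np.array(params.field_size) - margin, (n_fiducials, 2))
    beads_ch2 = beads @ lin.T + off + rng.normal(0, fiducial_jitter_nm, (n_fiducials, 2))
    reg = tracking.estimate_registration(
        list(zip(map(tuple, beads), map(tuple, beads_ch2)))
    )

    spots1 = _detect_channel(rec, params, "ch1", seed=params.seed * 1000 + 1,
                             snr_threshold=snr_threshold)
    spots2 = _detect_channel(ada, params, "ch2", seed=params.seed * 1000 + 2,
                             snr_threshold=snr_threshold)
    recall, rmse = _detection_metrics(spots1, truth.true_tracks_receptor)
    spots2 = tracking.apply_registration(reg, spots2)

    dt = params.frame_interval
    gate1 = max(
        4.0 * np.sqrt(4.0 * params.diffusion_receptor * dt), 4.0 * PIXEL_SIZE_NM
    )
    gate2 = 4.0 * np.sqrt(4.0 * params.diffusion_adaptor * dt)
    dedupe = 2.0 * PIXEL_SIZE_NM
    tracks1 = tracking.link_tracks(spots1, gate1, max_gap, min_track_length, dt,
                                   interpolate_gaps=True, dedupe_radius=dedupe)
    tracks2 = tracking.link_tracks(spots2, gate2, max_gap, min_track_length, dt,
                                   interpolate_gaps=True, dedupe_radius=dedupe)

    events = coloc.detect_coloc_events(tracks2, tracks1, cfg)
    fit = coloc.fit_exponential_survival(events, cfg)
    scores = synthetic.score_events_against_truth(
        truth, events, tracks2, min_duration=cfg.min_duration
    )
    return EndToEndResult(
        survival_fit=fit,
        event_scores=scores,
        detection_recall=recall,
        localization_rmse_nm=rmse,
        n_events=len(events),
        events=events,
    )
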