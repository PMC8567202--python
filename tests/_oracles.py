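"""Independent brute-force oracles shared across test modules.

These deliberately use naive enumeration / grid search, not the library's
own numerics, so they can stand as independent references.
"""

import math

import numpy as np

from memquant.binding import langmuir_fraction


def grid_search_kd(conc, resp, grid, free_amplitude=False):
    """Brute-force SSE minimiser over a Kd grid."""
    best_kd, best_sse = None, np.inf
    for kd in grid:
        f = langmuir_fraction(conc, kd)
        if free_amplitude:
            denom = float(f @ f)
            amp = float(f @ resp) / denom if denom > 0 else 1.0
        else:
            amp = 1.0
        sse = float(np.sum((amp * f - resp) ** 2))
        if sse < best_sse:
            best_kd, best_sse = kd, sse
    return best_kd


def brute_force_events(smad, receptor, cfg):
    """Frame-by-frame enumeration of colocalization runs (naive loops).

    Returns sorted (smad_id, receptor_id, start_frame, end_frame) tuples
    for runs strictly longer than ``cfg.min_duration``.
    """
    frames = sorted(set(smad["frame"]) | set(receptor["frame"]))
    assign = {}
    for f in frames:
        for sid in sorted(smad[smad.frame == f]["track_id"].unique()):
            srow = smad[(smad.frame == f) & (smad.track_id == sid)].iloc[0]
            best = None
            for rid in sorted(receptor[receptor.frame == f]["track_id"].unique()):
                rrow = receptor[(receptor.frame == f) & (receptor.track_id == rid)].iloc[0]
                d = math.hypot(srow.x_nm - rrow.x_nm, srow.y_nm - rrow.y_nm)
                if d < cfg.distance_threshold and (best is None or d < best[1]):
                    best = (rid, d)
            if best is not None:
                assign[(sid, f)] = best[0]
    events = []
    for sid in sorted(smad["track_id"].unique()):
        run = None
        for f in frames + [max(frames) + 2]:
            rid = assign.get((sid, f))
            if run is not None and (rid != run[0] or f != run[2] + 1):
                n = run[2] - run[1] + 1
                if n * cfg.frame_interval > cfg.min_duration:
                    events.append((sid, run[0], run[1], run[2]))
                run = None
            if rid is not None and run is None:
                run = [rid, f, f]
            elif rid is not None:
                run[2] = f
    return sorted(events)


def random_track_pair(rng, max_tracks=6, max_frames=51):
    """Small random two-channel track tables for oracle comparisons."""
    import pandas as pd

    n_sm = rng.integers(1, max_tracks)
    n_rc = rng.integers(1, max_tracks)
    n_frames = rng.integers(5, max_frames)
    rows_s, rows_r = [], []
    for sid in range(n_sm):
        x, y = rng.uniform(0, 2000, 2)
        for f in range(n_frames):
            x += rng.normal(0, 150)
            y += rng.normal(0, 150)
            rows_s.append((sid, f, x, y))
    for rid in range(n_rc):
        x, y = rng.uniform(0, 2000, 2)
        for f in range(n_frames):
            x += rng.normal(0, 80)
            y += rng.normal(0, 80)
            rows_r.append((rid, f, x, y))
    sm = pd.DataFrame(rows_s, columns=["track_id", "frame", "x_nm", "y_nm"])
    rc = pd.DataFrame(rows_r, columns=["track_id", "frame", "x_nm", "y_nm"])
    return sm, rc
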