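"""Spot detection, linking (with brute-force oracle) and registration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from memquant import synthetic, tracking
from memquant.errors import InvalidInputError
from memquant.tracking import (
    AffineTransform,
    apply_registration,
    detect_spots,
    estimate_registration,
    link_tracks,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_match_cost(last_xy, new_xy, gate):
    """Minimum of sum(d^2) + gate^2 * n_unmatched over all one-to-one matchings.

    Pairs farther than ``gate`` are inadmissible. Exhaustive enumeration —
    independent of the Hungarian-based implementation.
    """
    nt, ns = len(last_xy), len(new_xy)
    d2 = np.sum((last_xy[:, None, :] - new_xy[None, :, :]) ** 2, axis=2)
    best = np.inf
    for k in range(min(nt, ns) + 1):
        for tracks_sub in itertools.combinations(range(nt), k):
            for spots_perm in itertools.permutations(range(ns), k):
                if any(d2[t, s] > gate**2 for t, s in zip(tracks_sub, spots_perm)):
                    continue
                cost = sum(d2[t, s] for t, s in zip(tracks_sub, spots_perm))
                cost += gate**2 * (nt - k) + gate**2 * (ns - k)
                best = min(best, cost)
    return best


def assignment_cost(last_xy, new_xy, gate):
    """Cost realised by the production matcher, in the oracle's currency."""
    pairs = tracking._match_frame(
        last_xy, np.full(len(last_xy), gate), new_xy, gate
    )
    d2 = np.sum((last_xy[:, None, :] - new_xy[None, :, :]) ** 2, axis=2)
    cost = sum(d2[r, c] for r, c in pairs)
    unmatched = (len(last_xy) - len(pairs)) + (len(new_xy) - len(pairs))
    return cost + gate**2 * unmatched


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

class TestRegistration:
    def test_identity_from_identical_fiducials(self):
        pts = [(0.0, 0.0), (100.0, 0.0), (0.0, 100.0), (70.0, 30.0)]
        t = estimate_registration(list(zip(pts, pts)))
        assert np.allclose(t.linear, np.eye(2), atol=1e-12)
        assert np.allclose(t.offset, 0.0, atol=1e-9)
        assert t.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_recovered_from_three_pairs(self):
        p1 = [(0.0, 0.0), (100.0, 0.0), (0.0, 100.0)]
        p2 = [(x + 50.0, y - 30.0) for x, y in p1]
        t = estimate_registration(list(zip(p1, p2)))
        assert np.allclose(t.linear, np.eye(2), atol=1e-9)
        assert np.allclose(t.offset, [-50.0, 30.0], atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        p1 = rng.uniform(0, 20000, (20, 2))
        lin = np.array([[1.004, 0.002], [-0.001, 0.997]])
        off = np.array([35.0, -60.0])
        p2 = p1 @ lin.T + off + rng.normal(0, 5.0, (20, 2))
        t = estimate_registration(list(zip(map(tuple, p1), map(tuple, p2))))
        # closed-form normal equations, solved independently
        A = np.column_stack([p2, np.ones(20)])
        coef = np.linalg.solve(A.T @ A, A.T @ p1)
        assert np.allclose(t.linear, coef[:2].T, rtol=1e-9, atol=1e-12)
        assert np.allclose(t.offset, coef[2], rtol=1e-9, atol=1e-9)

    def test_too_few_or_collinear_pairs_rejected(self):
        with pytest.raises(InvalidInputError):
            estimate_registration([((0, 0), (0, 0)), ((1, 1), (1, 1))])
        col = [((float(i), float(i)), (float(i), float(i))) for i in range(5)]
        with pytest.raises(InvalidInputError):
            estimate_registration(col)

    def test_apply_then_inverse_is_identity(self):
        t = AffineTransform(np.array([[1.01, 0.03], [-0.02, 0.98]]), np.array([40.0, -25.0]))
        pts = np.random.default_rng(1).uniform(0, 1e4, (50, 2))
        back = t.inverse().apply(t.apply(pts))
        assert np.allclose(back, pts, atol=1e-9)

    def test_apply_registration_dataframe_records_transform(self):
        df = pd.DataFrame({"frame": [0], "x_nm": [10.0], "y_nm": [20.0]})
        t = AffineTransform(offset=np.array([5.0, -5.0]))
        out = apply_registration(t, df)
        assert out["x_nm"].iloc[0] == 15.0
        assert "registration" in out.attrs

    def test_registration_brings_bound_pairs_to_error_floor(self):
        """Round trip: distorted channel re-registered onto channel 1."""
        lin = np.array([[1.003, 0.001], [-0.002, 0.998]])
        off = np.array([60.0, -40.0])
        p = synthetic.TwoChannelSimParams(
            seed=3, n_frames=300, localization_error_sd=10.0,
            p_bind_per_frame=1.0, capture_radius=300.0,
            channel_transform=(lin, off),
        )
        rec, ada, truth = synthetic.simulate_two_channel_tracks(p)
        reg = AffineTransform(lin, off).inverse()
        ada_reg = apply_registration(reg, ada)
        iv = truth.true_bound_intervals
        rec_idx = rec.set_index(["particle_id", "frame"])
        ada_idx = ada_reg.set_index(["particle_id", "frame"])
        seps = []
        for row in iv.itertuples():
            for f in range(int(row.start_frame), int(row.end_frame) + 1):
                r = rec_idx.loc[(row.receptor_id, f)]
                a = ada_idx.loc[(row.adaptor_id, f)]
                seps.append(np.hypot(r.x_nm - a.x_nm, r.y_nm - a.y_nm))
        # two independent 10 nm errors -> median pair separation ~ 16 nm
        assert np.median(seps) < 3 * p.localization_error_sd

    def test_singular_linear_part_rejected(self):
        with pytest.raises(InvalidInputError):
            AffineTransform(np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

class TestDetection:
    def test_single_clean_spot_centroid(self):
        locs = pd.DataFrame({"frame": [0], "x_nm": [1575.0], "y_nm": [1630.0]})
        stack = synthetic.render_frames(
            locs, (3200.0, 3200.0), 130.0, 100.0, 0.0, 200000.0, seed=1
        )
        spots = detect_spots(stack, 130.0, 5.0, 100.0)
        assert len(spots) == 1
        assert spots["x_nm"].iloc[0] == pytest.approx(1575.0, abs=10.0)  # 0.1 px
        assert spots["y_nm"].iloc[0] == pytest.approx(1630.0, abs=10.0)

    def test_pure_background_yields_no_spots(self):
        rng_stack = synthetic.render_frames(
            pd.DataFrame(columns=["frame", "x_nm", "y_nm"]),
            (3200.0, 3200.0), 130.0, 100.0, 100.0, 1000.0, seed=2, n_frames=5,
        )
        spots = detect_spots(rng_stack, 130.0, 5.0, 100.0)
        assert len(spots) == 0

    def test_recall_and_rmse_at_snr_10(self):
        # 50 resolvable spots: jittered grid keeps pairs beyond the PSF reach
        rng = np.random.default_rng(12)
        n = 50
        field = (25600.0, 25600.0)
        gx, gy = np.meshgrid(np.linspace(1200, 24400, 8), np.linspace(1200, 24400, 8))
        centers = np.column_stack([gx.ravel(), gy.ravel()])[:n]
        centers += rng.uniform(-400, 400, centers.shape)
        locs = pd.DataFrame({
            "frame": np.zeros(n, dtype=int),
            "x_nm": centers[:, 0],
            "y_nm": centers[:, 1],
        })
        bg = 100.0
        photon = 10.0 * np.sqrt(bg) * 2 * np.pi * 1.3**2
        stack = synthetic.render_frames(locs, field, 130.0, 100.0, bg, photon, seed=3)
        spots = detect_spots(stack, 130.0, 5.0, 100.0)
        d = np.hypot(
            locs["x_nm"].to_numpy()[:, None] - spots["x_nm"].to_numpy()[None, :],
            locs["y_nm"].to_numpy()[:, None] - spots["y_nm"].to_numpy()[None, :],
        ).min(axis=1)
        hits = d < 100.0  # within 1 pixel
        assert hits.mean() >= 0.95
        assert np.sqrt(np.mean(d[hits] ** 2)) <= 50.0  # 0.5 pixel

    def test_rejects_bad_dimensionality(self):
        with pytest.raises(InvalidInputError):
            detect_spots(np.zeros(10), 130.0, 5.0, 100.0)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

class TestLinking:
    def _spots(self, rows):
        return pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"]).assign(channel="ch1")

    def test_single_stationary_spot_one_track(self):
        spots = self._spots([(f, 500.0, 500.0) for f in range(20)])
        tracks = link_tracks(spots, max_displacement=100.0, min_track_length=4)
        assert tracks["track_id"].nunique() == 1
        assert len(tracks) == 20

    def test_two_distant_spots_two_tracks_no_switches(self):
        rows = [(f, 0.0, 0.0) for f in range(10)] + [(f, 5000.0, 0.0) for f in range(10)]
        tracks = link_tracks(self._spots(rows), max_displacement=500.0)
        assert tracks["track_id"].nunique() == 2
        for _, g in tracks.groupby("track_id"):
            assert g["x_nm"].nunique() == 1

    def test_assignment_cost_equals_brute_force(self):
        """Random 5-spot instances: optimal matching cost == enumeration."""
        rng = np.random.default_rng(21)
        for _ in range(40):
            nt, ns = rng.integers(1, 6, 2)
            last = rng.uniform(0, 2000, (nt, 2))
            new = rng.uniform(0, 2000, (ns, 2))
            gate = rng.uniform(300, 1500)
            assert assignment_cost(last, new, gate) == pytest.approx(
                brute_force_match_cost(last, new, gate)
            )

    def test_permutation_invariance_within_frames(self):
        rng = np.random.default_rng(14)
        rows = []
        pos = rng.uniform(0, 5000, (6, 2))
        for f in range(6):
            pos = pos + rng.normal(0, 60, pos.shape)
            for x, y in pos:
                rows.append((f, x, y))
        spots = self._spots(rows)
        shuffled = spots.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = link_tracks(spots, 400.0).sort_values(["frame", "x_nm"]).reset_index(drop=True)
        b = link_tracks(shuffled, 400.0).sort_values(["frame", "x_nm"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a[["frame", "x_nm", "y_nm"]], b[["frame", "x_nm", "y_nm"]])

    def test_no_track_has_two_spots_in_one_frame(self):
        rng = np.random.default_rng(15)
        rows = [(f, x, y) for f in range(15)
                for x, y in rng.uniform(0, 3000, (4, 2))]
        tracks = link_tracks(self._spots(rows), 2000.0, min_track_length=1)
        dup = tracks.groupby(["track_id", "frame"]).size()
        assert (dup == 1).all()

    def test_gap_closing_and_interpolation(self):
        rows = [(f, 100.0, 100.0) for f in range(10) if f != 5]
        tracks = link_tracks(self._spots(rows), 100.0, max_gap=1,
                             min_track_length=4, interpolate_gaps=True)
        assert tracks["track_id"].nunique() == 1
        assert set(tracks["frame"]) == set(range(10))
        interp = tracks[tracks["frame"] == 5]
        assert interp["x_nm"].iloc[0] == pytest.approx(100.0)

    def test_short_tracks_discarded(self):
        rows = [(0, 0.0, 0.0), (1, 0.0, 0.0)]
        tracks = link_tracks(self._spots(rows), 100.0, min_track_length=4)
        assert len(tracks) == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(InvalidInputError):
            link_tracks(self._spots([(0, 0.0, 0.0)]), -1.0)

    def test_phantom_track_suppression(self):
        """A parallel shadow within the dedupe radius is removed."""
        rows = [(f, 1000.0 + 10 * f, 1000.0) for f in range(20)]
        rows += [(f, 1030.0 + 10 * f, 1020.0) for f in range(20)]
        spots = self._spots(rows)
        plain = link_tracks(spots, 300.0, min_track_length=4)
        deduped = link_tracks(spots, 300.0, min_track_length=4, dedupe_radius=100.0)
        assert plain["track_id"].nunique() == 2
        assert deduped["track_id"].nunique() == 1


class TestEndToEndTracking:
    def test_track_recovery_on_synthetic_movie(self):
        """Detection + linking + registration recovers >= 90% of ground truth."""
        lin = np.array([[1.002, -0.001], [0.001, 0.998]])
        off = np.array([30.0, -20.0])
        p = synthetic.TwoChannelSimParams(
            seed=17, n_frames=60, n_receptors=15, n_adaptors=0,
            diffusion_receptor=1e5, field_size=(25600.0, 25600.0),
            localization_error_sd=0.0, channel_transform=(lin, off),
        )
        rec, _, truth = synthetic.simulate_two_channel_tracks(p)
        bg = 100.0
        photon = 10.0 * np.sqrt(bg) * 2 * np.pi * 1.3**2
        stack = synthetic.render_frames(rec, p.field_size, 130.0, 100.0, bg, photon,
                                        seed=4, n_frames=p.n_frames)
        spots = detect_spots(stack, 130.0, 5.0, 100.0)
        tracks = link_tracks(spots, 400.0, max_gap=2, min_track_length=4,
                             interpolate_gaps=True, dedupe_radius=200.0)
        true_idx = truth.true_tracks_receptor.set_index(["particle_id", "frame"])
        recovered = 0
        for pid in range(p.n_receptors):
            tp = truth.true_tracks_receptor[truth.true_tracks_receptor.particle_id == pid]
            best = 0.0
            for tid, g in tracks.groupby("track_id"):
                m = g.merge(tp, on="frame", suffixes=("", "_t"))
                if not len(m):
                    continue
                close = np.hypot(m.x_nm - m.x_nm_t, m.y_nm - m.y_nm_t) < 200.0
                jaccard = close.sum() / len(tp)
                best = max(best, jaccard)
            if best >= 0.8:
                recovered += 1
        assert recovered >= 0.9 * p.n_receptors
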