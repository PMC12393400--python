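"""Track parsing, carry-forward imputation, and the distance-to-peak outcome."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from wormassay import simulate, tracks
from wormassay.tracks import (
    AssayGeometry,
    impute_carry_forward,
    parse_tracks,
    plate_summary,
    worm_outcome,
    write_tracks,
)


def make_track(track_id, positions, frame_rate=3.75):
    """positions: dict frame -> (x, y) or None for an undetected frame."""
    rows = []
    for frame, pos in sorted(positions.items()):
        x, y = pos if pos is not None else (np.nan, np.nan)
        rows.append(
            {
                "track_id": track_id,
                "frame": frame,
                "time_s": frame / frame_rate,
                "x_mm": x,
                "y_mm": y,
                "detected": pos is not None,
            }
        )
    return pd.DataFrame(rows)


def brute_force_outcome(track, geometry):
    """Independent re-implementation of the outcome: explicit frame loop."""
    w_first, w_last = geometry.window_frames
    detected = {
        int(r.frame): (r.x_mm, r.y_mm)
        for r in track.itertuples()
        if r.detected and r.frame <= w_last
    }
    if not detected:
        return None
    first_det = min(detected)
    px, py = geometry.peak_xy_mm
    distances = []
    last_pos = None
    for f in range(first_det, w_last + 1):
        if f in detected:
            last_pos = detected[f]
        if f >= w_first and last_pos is not None:
            distances.append(math.hypot(last_pos[0] - px, last_pos[1] - py))
    return sum(distances) / len(distances) if distances else None


GEOM = AssayGeometry(peak_xy_mm=(12.5, 0.0))


class TestParse:
    def test_two_track_file(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "track_id,frame,time_s,x_mm,y_mm\n"
            "1,0,0.0,1.0,2.0\n1,1,0.266,1.1,2.1\n"
            "2,0,0.0,-3.0,4.0\n2,1,0.266,-3.1,4.2\n"
        )
        table = parse_tracks(path)
        assert sorted(table["track_id"].unique()) == [1, 2]
        assert table["detected"].all()

    def test_blank_coordinates_marked_undetected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("track_id,frame,time_s,x_mm,y_mm\n1,0,0.0,1.0,2.0\n1,1,0.266,,\n")
        table = parse_tracks(path)
        assert list(table["detected"]) == [True, False]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("track_id,frame\n1,0\n")
        with pytest.raises(ValueError, match="missing mandatory columns"):
            parse_tracks(path)

    def test_duplicate_rows_rejected_with_offenders(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("track_id,frame,x_mm,y_mm\n1,0,1,1\n1,0,2,2\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_tracks(path)

    def test_column_map_dialect(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("Track,Frame,X,Y\n7,0,1.0,2.0\n")
        table = parse_tracks(path, column_map={"track_id": "Track", "frame": "Frame", "x": "X", "y": "Y"})
        assert table["track_id"].iloc[0] == 7

    def test_roundtrip_identity_on_simulated_tracks(self, tmp_path, standard_field):
        cfg = simulate.SimConfig(n_worms=4, rng_seed=1, gap_probability_per_frame=0.01)
        tt = simulate.simulate_chemotaxis_tracks(cfg, simulate.WormParams(), standard_field)
        path = tmp_path / "sim.csv"
        write_tracks(tt, path)
        back = parse_tracks(path)
        pd.testing.assert_frame_equal(
            back[["track_id", "frame", "x_mm", "y_mm", "detected"]],
            tt[["track_id", "frame", "x_mm", "y_mm", "detected"]],
        )


class TestImputation:
    def test_hand_walked_carry_forward(self):
        track = make_track(1, {0: (0.0, 0.0), 1: None, 2: None, 3: (3.0, 0.0)})
        series = impute_carry_forward(track, (0, 3))
        assert list(zip(series["x_mm"], series["y_mm"])) == [
            (0.0, 0.0),
            (0.0, 0.0),
            (0.0, 0.0),
            (3.0, 0.0),
        ]
        assert list(series["imputed"]) == [False, True, True, False]

    def test_gap_free_series_is_identity(self):
        track = make_track(1, {f: (float(f), 1.0) for f in range(5)})
        series = impute_carry_forward(track, (0, 4))
        assert np.array_equal(series["x_mm"], track["x_mm"])
        assert not series["imputed"].any()

    def test_terminal_gap_repeats_last_position(self):
        track = make_track(1, {0: (1.0, 1.0), 1: (2.0, 1.0), 2: None, 3: None})
        series = impute_carry_forward(track, (0, 3))
        assert list(series["x_mm"]) == [1.0, 2.0, 2.0, 2.0]

    def test_frames_before_first_detection_excluded(self):
        track = make_track(1, {0: None, 1: None, 2: (5.0, 0.0), 3: (6.0, 0.0)})
        series = impute_carry_forward(track, (0, 3))
        assert list(series["frame"]) == [2, 3]

    def test_never_detected_track_returns_none(self):
        track = make_track(1, {0: None, 1: None})
        assert impute_carry_forward(track, (0, 1)) is None

    def test_imputed_positions_come_from_detected_set(self, standard_field):
        cfg = simulate.SimConfig(n_worms=3, rng_seed=6, gap_probability_per_frame=0.02)
        tt = simulate.simulate_chemotaxis_tracks(cfg, simulate.WormParams(), standard_field)
        for _, track in tt.groupby("track_id"):
            series = impute_carry_forward(track, (0, cfg.n_frames - 1))
            observed = set(
                zip(track.loc[track["detected"], "x_mm"], track.loc[track["detected"], "y_mm"])
            )
            assert set(zip(series["x_mm"], series["y_mm"])) <= observed


class TestOutcome:
    def test_stationary_worm_distance(self):
        track = make_track(1, {f: (12.5 + 7.0, 0.0) for f in range(GEOM.n_frames)})
        rec = worm_outcome(track, GEOM)
        assert rec.mean_distance_mm == pytest.approx(7.0)
        assert rec.n_frames_in_window == 225

    def test_worm_at_peak_scores_zero(self):
        track = make_track(1, {f: GEOM.peak_xy_mm for f in range(GEOM.n_frames)})
        assert worm_outcome(track, GEOM).mean_distance_mm == pytest.approx(0.0)

    def test_three_frame_window_mean(self):
        geom = AssayGeometry(
            peak_xy_mm=(0.0, 0.0), assay_duration_s=3.0, frame_rate_fps=1.0, window_length_s=3.0
        )
        track = make_track(1, {0: (4.0, 0.0), 1: (6.0, 0.0), 2: (8.0, 0.0)})
        assert worm_outcome(track, geom).mean_distance_mm == pytest.approx(6.0)

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(12)
        geom = AssayGeometry(
            peak_xy_mm=(5.0, -3.0), assay_duration_s=50.0, frame_rate_fps=1.0, window_length_s=20.0
        )
        for _ in range(25):
            n_frames = int(rng.integers(5, 50))
            positions = {}
            for f in range(n_frames):
                if rng.uniform() < 0.3:
                    positions[f] = None
                else:
                    positions[f] = tuple(rng.uniform(-10, 10, 2))
            track = make_track(1, positions, frame_rate=1.0)
            expected = brute_force_outcome(track, geom)
            rec = worm_outcome(track, geom)
            if expected is None:
                assert rec is None
            else:
                assert rec.mean_distance_mm == pytest.approx(expected, abs=1e-12)

    def test_translation_and_rotation_invariance(self, standard_field):
        cfg = simulate.SimConfig(n_worms=5, rng_seed=3, gap_probability_per_frame=0.01)
        tt = simulate.simulate_chemotaxis_tracks(cfg, simulate.WormParams(), standard_field)
        geom = AssayGeometry(peak_xy_mm=standard_field.peak_xy_mm)
        base, _ = plate_summary(tt, geom)

        shifted = tt.copy()
        shifted["x_mm"] += 4.0
        shifted["y_mm"] -= 2.5
        geom_shift = AssayGeometry(peak_xy_mm=(geom.peak_xy_mm[0] + 4.0, geom.peak_xy_mm[1] - 2.5))
        moved, _ = plate_summary(shifted, geom_shift)
        assert np.allclose(base["mean_distance_mm"], moved["mean_distance_mm"])

        theta = 0.7
        px, py = geom.peak_xy_mm
        rot = tt.copy()
        dx, dy = tt["x_mm"] - px, tt["y_mm"] - py
        rot["x_mm"] = px + dx * math.cos(theta) - dy * math.sin(theta)
        rot["y_mm"] = py + dx * math.sin(theta) + dy * math.cos(theta)
        rotated, _ = plate_summary(rot, geom)
        assert np.allclose(base["mean_distance_mm"], rotated["mean_distance_mm"])


class TestPlateSummary:
    def test_two_stationary_worms(self):
        t1 = make_track(1, {f: (12.5 + 4.0, 0.0) for f in range(GEOM.n_frames)})
        t2 = make_track(2, {f: (12.5 + 8.0, 0.0) for f in range(GEOM.n_frames)})
        records, agg = plate_summary(pd.concat([t1, t2], ignore_index=True), GEOM)
        assert agg["mean_distance_mm"] == pytest.approx(6.0)
        assert agg["n_worms"] == 2

    def test_never_detected_track_excluded(self):
        t1 = make_track(1, {f: (15.0, 0.0) for f in range(GEOM.n_frames)})
        t2 = make_track(2, {f: None for f in range(GEOM.n_frames)})
        records, agg = plate_summary(pd.concat([t1, t2], ignore_index=True), GEOM)
        assert agg["n_worms"] == 1
        assert agg["n_excluded"] == 1

    def test_empty_table(self):
        records, agg = plate_summary(pd.DataFrame(columns=simulate.TRACK_COLUMNS), GEOM)
        assert len(records) == 0 and agg["n_worms"] == 0

    def test_chemotaxis_gain_lowers_plate_mean(self, standard_field):
        geom = AssayGeometry(peak_xy_mm=standard_field.peak_xy_mm)

        def plate_mean(beta):
            cfg = simulate.SimConfig(n_worms=60, rng_seed=21)
            tt = simulate.simulate_chemotaxis_tracks(
                cfg, simulate.WormParams(chemotaxis_gain_beta=beta), standard_field
            )
            _, agg = plate_summary(tt, geom)
            return agg["mean_distance_mm"]

        assert plate_mean(2.0) < plate_mean(0.0)
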