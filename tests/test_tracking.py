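"""Spot linking against an exhaustive matching oracle; track statistics."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from filotip import synthetic_data as syn
from filotip.tracking import Track, link_spots, per_cell_summary, track_stats


def spot_table(rows, cell="c0"):
    """rows: iterable of (frame, x, y)."""
    return pd.DataFrame(
        [(cell, f, x, y) for f, x, y in rows],
        columns=["cell_id", "frame", "x_um", "y_um"],
    )


def oracle_frame_links(a, b, max_link):
    """Exhaustive minimum-cost matching between two frames.

    Enumerates every injective assignment of sources to targets using
    only pairs within ``max_link``; each unlinked spot pays the no-link
    alternative cost 1.05 × max_link.  Returns the optimal
    (n_links, total_link_distance, total_cost).
    """
    from itertools import combinations

    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    no_link = 1.05 * max_link
    best = (0, 0.0, (n + m) * no_link)
    for size in range(min(n, m) + 1):
        for src in combinations(range(n), size):
            for tgt_perm in permutations(range(m), size):
                d = [np.linalg.norm(a[i] - b[j]) for i, j in zip(src, tgt_perm)]
                if all(x <= max_link for x in d):
                    cost = sum(d) + no_link * (n + m - 2 * size)
                    if cost < best[2] - 1e-12:
                        best = (size, sum(d), cost)
    return best


class TestLinkSpots:
    def test_single_stationary_spot(self):
        spots = spot_table([(f, 0.0, 0.0) for f in range(12)])
        tracks = link_spots(spots)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 12

    def test_step_beyond_max_link_splits(self):
        # a 1.2-µm jump with a 1.0-µm limit: link refused, two tracks
        spots = spot_table([(0, 0.0, 0.0), (1, 1.2, 0.0)])
        tracks = link_spots(spots, max_link_um=1.0)
        assert len(tracks) == 2

    def test_step_within_max_link_links(self):
        spots = spot_table([(0, 0.0, 0.0), (1, 0.9, 0.0)])
        assert len(link_spots(spots, max_link_um=1.0)) == 1

    def test_two_distant_tracks_stay_separate(self):
        rows = [(f, 0.0, 0.0) for f in range(5)] + [(f, 20.0, 0.0) for f in range(5)]
        tracks = link_spots(spot_table(rows))
        assert len(tracks) == 2
        assert sorted(t.n_frames for t in tracks) == [5, 5]

    def test_matches_exhaustive_matching_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n, m = rng.integers(1, 5, size=2)
            a = rng.uniform(0, 3, size=(n, 2))
            b = rng.uniform(0, 3, size=(m, 2))
            rows = [(0, x, y) for x, y in a] + [(1, x, y) for x, y in b]
            tracks = link_spots(spot_table(rows), max_link_um=1.0)
            n_links = sum(1 for t in tracks if t.n_frames == 2)
            total = sum(t.total_distance_um for t in tracks)
            cost = total + 1.05 * (n + m - 2 * n_links)
            o_links, o_total, o_cost = oracle_frame_links(a, b, 1.0)
            assert cost == pytest.approx(o_cost, abs=1e-9)
            assert n_links == o_links
            assert total == pytest.approx(o_total, abs=1e-9)

    def test_every_spot_in_exactly_one_track(self):
        rng = np.random.default_rng(4)
        rows = [
            (f, float(x), float(y))
            for f in range(6)
            for x, y in rng.uniform(0, 10, size=(4, 2))
        ]
        spots = spot_table(rows)
        tracks = link_spots(spots)
        linked = sum(t.n_frames for t in tracks)
        assert linked == len(spots)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        rows = [
            (f, float(x), float(y))
            for f in range(4)
            for x, y in rng.uniform(0, 5, size=(3, 2))
        ]
        t0 = link_spots(spot_table(rows))
        shifted = [(f, x + 100.0, y - 50.0) for f, x, y in rows]
        t1 = link_spots(spot_table(shifted))
        assert len(t0) == len(t1)
        for a, b in zip(t0, t1):
            np.testing.assert_array_equal(a.frames, b.frames)
            np.testing.assert_allclose(a.positions + [100.0, -50.0], b.positions)

    def test_identity_recovery_noise_free(self):
        # well-separated noise-free walkers are recovered exactly
        gts = syn.random_walk_tracks(9, n_frames=15, step_sd_um=0.1,
                                     spacing_um=5.0, seed=3)
        spots = syn.generate_tracks(gts, detection_noise_um=0.0)
        tracks = link_spots(spots, max_link_um=1.0)
        assert len(tracks) == 9
        # partition must equal ground truth: map each recovered track to the
        # truth labels of its spots
        key = {(r.frame, round(r.x_um, 9), round(r.y_um, 9)): r.truth_track
               for r in spots.itertuples()}
        for t in tracks:
            labels = {
                key[(int(f), round(x, 9), round(y, 9))]
                for f, (x, y) in zip(t.frames, t.positions)
            }
            assert len(labels) == 1

    def test_negative_max_link_rejected(self):
        with pytest.raises(ValueError):
            link_spots(spot_table([(0, 0.0, 0.0)]), max_link_um=-1.0)

    def test_cells_tracked_independently(self):
        rows = pd.concat(
            [spot_table([(f, 0.0, 0.0) for f in range(3)], cell="c0"),
             spot_table([(f, 0.0, 0.0) for f in range(3)], cell="c1")],
            ignore_index=True,
        )
        tracks = link_spots(rows)
        assert sorted(t.cell_id for t in tracks) == ["c0", "c1"]


class TestTrackStats:
    def test_single_step(self):
        t = Track(0, "c0", [0, 1], [[0.0, 0.0], [1.0, 0.0]], frame_interval_s=5.0)
        assert track_stats(t) == (5.0, 1.0, pytest.approx(0.2))

    def test_single_frame(self):
        t = Track(0, "c0", [0], [[2.0, 3.0]])
        assert track_stats(t) == (0.0, 0.0, 0.0)

    def test_random_track_matches_step_sum(self):
        rng = np.random.default_rng(6)
        pos = rng.uniform(0, 5, size=(8, 2))
        t = Track(0, "c0", np.arange(8), pos, frame_interval_s=5.0)
        dur, dist, speed = track_stats(t)
        dist_oracle = sum(
            float(np.hypot(*(pos[i + 1] - pos[i]))) for i in range(7)
        )
        assert dur == 35.0
        assert dist == pytest.approx(dist_oracle)
        assert speed == pytest.approx(dist_oracle / 35.0)

    def test_gapped_frames_rejected(self):
        with pytest.raises(ValueError):
            Track(0, "c0", [0, 2], [[0.0, 0.0], [1.0, 0.0]])


class TestPerCellSummary:
    def test_mean_duration(self):
        t1 = Track(0, "c0", [0, 1], np.zeros((2, 2)), frame_interval_s=5.0)
        t2 = Track(1, "c0", np.arange(4), np.zeros((4, 2)), frame_interval_s=5.0)
        out = per_cell_summary([t1, t2])
        assert len(out) == 1
        assert out["mean_duration_s"].iloc[0] == pytest.approx(10.0)

    def test_cells_are_independent_rows(self):
        t1 = Track(0, "c0", [0], np.zeros((1, 2)))
        t2 = Track(1, "c1", [0], np.zeros((1, 2)))
        out = per_cell_summary([t1, t2])
        assert sorted(out["cell_id"]) == ["c0", "c1"]

    def test_recovers_planted_per_cell_mean(self):
        gts = syn.random_walk_tracks(4, n_frames=10, step_sd_um=0.05,
                                     spacing_um=5.0, frame_interval_s=5.0, seed=8)
        spots = syn.generate_tracks(gts, detection_noise_um=0.0)
        tracks = link_spots(spots, max_link_um=1.0, frame_interval_s=5.0)
        out = per_cell_summary(tracks)
        truth_dist = np.mean(
            [np.sum(np.linalg.norm(np.diff(g.positions, axis=0), axis=1)) for g in gts]
        )
        assert out["mean_duration_s"].iloc[0] == pytest.approx(45.0)
        assert out["mean_distance_um"].iloc[0] == pytest.approx(truth_dist)
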