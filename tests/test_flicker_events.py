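import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nestflick.flicker_events import (EventFilterConfig, FlickerEvent,
                                      ShimmerEpisode, activity_fraction,
                                      detect_events, detect_events_grid,
                                      detect_shimmer_episodes, filter_events)


def naive_detect(series, threshold=2.0, max_duration=3, gap_frames=50.0):
    """Independent run-scan oracle: linear walk, then onset-gap merging."""
    events = []
    i = 0
    while i < len(series):
        if series[i] > threshold:
            j = i
            while j < len(series) and series[j] > threshold:
                j += 1
            if j - i <= max_duration:
                events.append((i, j - i, max(series[i:j]), sum(series[i:j])))
            i = j
        else:
            i += 1
    merged = []
    for ev in events:
        if merged and ev[0] - merged[-1][0] < gap_frames:
            prev = merged[-1]
            merged[-1] = (prev[0], prev[1], max(prev[2], ev[2]), prev[3] + ev[3])
        else:
            merged.append(ev)
    return merged


class TestDetectEvents:
    def test_single_pulse(self):
        cfg = EventFilterConfig()
        events = detect_events([0, 0, 3, 0, 0], cfg)
        assert len(events) == 1
        ev = events[0]
        assert (ev.onset_frame, ev.duration_frames) == (2, 1)
        assert ev.peak_dlum == ev.sum_dlum == 3.0

    def test_sustained_run_rejected(self):
        # four supra-threshold frames: fanning-like motion, not a flicker
        cfg = EventFilterConfig()
        assert detect_events([0, 5, 5, 5, 5, 0], cfg) == []

    def test_three_frame_run_is_still_an_event(self):
        cfg = EventFilterConfig()
        events = detect_events([0, 5, 5, 5, 0], cfg)
        assert len(events) == 1
        assert events[0].duration_frames == 3
        assert events[0].sum_dlum == 15.0

    def test_duration_bound_in_milliseconds(self):
        assert EventFilterConfig(fps=50.0).max_duration_ms() == pytest.approx(60.0)
        assert EventFilterConfig(fps=25.0).max_duration_ms() == pytest.approx(120.0)

    def test_threshold_is_strict(self):
        cfg = EventFilterConfig(detect_threshold=2.0)
        assert detect_events([0, 2.0, 0], cfg) == []
        assert len(detect_events([0, 2.01, 0], cfg)) == 1

    def test_refractory_merging(self):
        cfg = EventFilterConfig(min_gap_s=1.0, fps=50.0)
        series = np.zeros(100)
        series[10] = 4.0
        series[40] = 6.0  # 30 frames later: inside the 50-frame window
        events = detect_events(series, cfg)
        assert len(events) == 1
        assert events[0].onset_frame == 10
        assert events[0].peak_dlum == 6.0
        assert events[0].sum_dlum == 10.0

    def test_events_beyond_refractory_kept_separate(self):
        cfg = EventFilterConfig(min_gap_s=1.0, fps=50.0)
        series = np.zeros(200)
        series[10] = 4.0
        series[70] = 6.0
        assert len(detect_events(series, cfg)) == 2

    def test_matches_run_scan_oracle_on_random_series(self, rng):
        cfg = EventFilterConfig()
        for _ in range(50):
            series = np.where(rng.random(80) < 0.3, rng.uniform(0, 10, 80), 0.0)
            got = [(e.onset_frame, e.duration_frames, e.peak_dlum, e.sum_dlum)
                   for e in detect_events(series, cfg)]
            want = [(o, d, pytest.approx(p), pytest.approx(s))
                    for o, d, p, s in naive_detect(series.tolist())]
            assert got == want

    @given(st.lists(st.floats(0, 20), min_size=5, max_size=60),
           st.floats(1, 10), st.floats(0.1, 9))
    def test_raising_threshold_never_adds_events(self, series, low, extra):
        cfg_low = EventFilterConfig(detect_threshold=low)
        cfg_high = EventFilterConfig(detect_threshold=low + extra)
        assert len(detect_events(series, cfg_high)) <= len(detect_events(series, cfg_low))

    def test_first_frame_index_offsets_onsets(self):
        events = detect_events([0, 3, 0], EventFilterConfig(), first_frame_index=1)
        assert events[0].onset_frame == 2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            EventFilterConfig(fps=0)
        with pytest.raises(ValueError):
            detect_events([0, -1, 0], EventFilterConfig())
        with pytest.raises(ValueError):
            detect_events([0, np.nan, 0], EventFilterConfig())


class TestShimmerEpisodes:
    def test_constant_zero_activity(self):
        assert detect_shimmer_episodes(np.zeros(50)) == []

    def test_zero_threshold_spans_all_frames(self):
        eps = detect_shimmer_episodes(np.zeros(50), frac_threshold=0.0)
        assert len(eps) == 1
        assert (eps[0].start_frame, eps[0].end_frame) == (0, 50)

    def test_short_bursts_below_min_length_dropped(self):
        frac = np.zeros(30)
        frac[5:7] = 0.5
        assert detect_shimmer_episodes(frac, frac_threshold=0.2, min_len_frames=3) == []
        assert len(detect_shimmer_episodes(frac, frac_threshold=0.2,
                                           min_len_frames=2)) == 1

    def test_episodes_sorted_and_disjoint(self):
        frac = np.zeros(60)
        frac[10:15] = 0.9
        frac[40:48] = 0.5
        eps = detect_shimmer_episodes(frac, frac_threshold=0.2)
        assert [(e.start_frame, e.end_frame) for e in eps] == [(10, 15), (40, 48)]

    def test_boolean_matrix_yields_participating_squares(self):
        mat = np.zeros((20, 2, 2), dtype=bool)
        mat[5:10, 0, 1] = True
        mat[5:10, 1, 1] = True
        eps = detect_shimmer_episodes(mat, frac_threshold=0.5, min_len_frames=3)
        assert len(eps) == 1
        assert eps[0].participating == frozenset({(0, 1), (1, 1)})

    def test_wave_sweep_is_masked(self):
        """A synthetic radial wave becomes exactly one episode over its sweep."""
        import nestflick as nf
        cfg = nf.SceneConfig(grid_rows=8, grid_cols=8, n_frames=200, square_px=8,
                             noise_sd=0.0,
                             waves=(nf.WaveSpec(trigger_square=(4, 4), start_frame=100,
                                                speed=1.0, participation_prob=1.0),),
                             seed=0)
        series, gt = nf.render_square_series(cfg)
        frac = activity_fraction(series, 2.0)
        eps = detect_shimmer_episodes(frac, frac_threshold=0.15, min_len_frames=3,
                                      first_frame_index=1)
        assert len(eps) == 1
        onsets = [e.onset_frame for e in gt.events if e.kind == "wave_flip"]
        # the episode lies within the sweep and covers its high-activity core
        assert min(onsets) <= eps[0].start_frame
        assert eps[0].end_frame <= max(onsets) + 1
        assert eps[0].end_frame - eps[0].start_frame >= 3

    def test_invalid_episode_bounds_rejected(self):
        with pytest.raises(ValueError):
            ShimmerEpisode(start_frame=5, end_frame=5)


class TestFilterEvents:
    def _ev(self, square, onset, duration=1):
        return FlickerEvent(square=square, onset_frame=onset,
                            duration_frames=duration, peak_dlum=5.0, sum_dlum=5.0)

    def test_identity_without_masks_or_episodes(self):
        events = [self._ev((0, 0), 5), self._ev((1, 1), 50)]
        assert filter_events(events) == events

    def test_event_inside_episode_removed(self):
        ep = ShimmerEpisode(start_frame=40, end_frame=60)
        events = [self._ev((0, 0), 45), self._ev((0, 0), 70)]
        assert filter_events(events, [ep]) == [events[1]]

    def test_boundary_overlap_is_half_open(self):
        ep = ShimmerEpisode(start_frame=40, end_frame=60)
        assert filter_events([self._ev((0, 0), 60)], [ep]) != []  # starts at end: kept
        assert filter_events([self._ev((0, 0), 39, duration=2)], [ep]) == []

    def test_masked_square_removed(self):
        events = [self._ev((0, 0), 5), self._ev((2, 2), 5)]
        assert filter_events(events, [], active_squares={(0, 0)}) == [events[0]]

    def test_idempotence(self):
        ep = ShimmerEpisode(start_frame=10, end_frame=20)
        events = [self._ev((0, 0), 5), self._ev((0, 0), 15), self._ev((3, 3), 90)]
        once = filter_events(events, [ep], active_squares={(0, 0), (3, 3)})
        twice = filter_events(once, [ep], active_squares={(0, 0), (3, 3)})
        assert once == twice
        assert set(once) <= set(events)

    def test_ground_truth_bookkeeping_with_wave(self):
        """Exactly the wave-colliding detections are dropped, flickers survive."""
        import nestflick as nf
        # flicker squares kept outside the wave's radius so no square mixes kinds
        flicker_squares = tuple((r, c) for r in range(10) for c in range(10)
                                if max(abs(r - 5), abs(c - 5)) >= 5)
        cfg = nf.SceneConfig(
            grid_rows=10, grid_cols=10, n_frames=600, square_px=8, noise_sd=0.0,
            cohorts=(nf.CohortSpec(squares=flicker_squares, flicker_rate=0.2),),
            waves=(nf.WaveSpec(trigger_square=(5, 5), start_frame=300, speed=1.0,
                               participation_prob=1.0, max_radius=4),),
            seed=11)
        series, gt = nf.render_square_series(cfg)
        cfgf = nf.EventFilterConfig()
        frac = activity_fraction(series, cfgf.detect_threshold)
        eps = detect_shimmer_episodes(frac, 0.15, 3, first_frame_index=1)
        assert len(eps) == 1
        detected = detect_events_grid(series, cfgf)
        kept = filter_events(detected, eps)
        dropped = [e for e in detected if e not in kept]
        assert all(eps[0].overlaps(e.onset_frame, e.duration_frames) for e in dropped)
        truth_clear = [e for e in gt.flickers()
                       if not eps[0].overlaps(e.onset_frame, e.duration_frames)]
        m = nf.match_events(truth_clear, kept)
        assert m.recall == 1.0
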