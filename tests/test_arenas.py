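import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swimassay import (
    ARENA_PRESETS,
    Track,
    assign_zones,
    extract_visits,
    get_arena,
    session_metrics,
    visits_from_track,
)
from swimassay.arenas import ArenaSpec, Zone
from swimassay.synth import SimConfig, simulate_visits

from conftest import track_from_labels


class TestPresets:
    @pytest.mark.parametrize("assay", sorted(ARENA_PRESETS))
    def test_preset_is_valid(self, assay):
        """All built-in arenas pass their own invariant checks."""
        arena = get_arena(assay)
        arena.validate()
        # adjacency symmetric by construction (frozensets) and within ids
        for pair in arena.adjacency:
            assert len(pair) == 2
        for zid in arena.labels:
            arena.zone(zid)

    def test_ot_central_circle_covers_80_percent(self, ot_arena):
        """Open tank: central radius ratio is sqrt(0.8), area ratio 80%."""
        r_center = ot_arena.zone("center").params[2]
        r_total = ot_arena.zone("periphery").params[3]
        assert r_center / r_total == pytest.approx(math.sqrt(0.8), abs=1e-12)
        area_ratio = (r_center / r_total) ** 2
        assert area_ratio == pytest.approx(0.8, abs=1e-9)

    def test_slalom_has_12_chambers_of_printed_size(self):
        arena = get_arena("slalom")
        chambers = [z for z in arena.zones]
        assert len(chambers) == 12
        total_len = sum(z.params[2] - z.params[0] for z in chambers)
        assert total_len == pytest.approx(85.0)

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            ArenaSpec(
                "bad",
                [Zone("a", "rectangle", (0, 0, 2, 2)),
                 Zone("b", "rectangle", (1, 1, 3, 3))],
            )


class TestAssignZones:
    def test_ot_center_point_is_center(self, ot_arena):
        """The arena midpoint lies inside any concentric central circle."""
        tr = Track("s", "x", [0.0, 0.1], [17.5, 17.5], [17.5, 17.5])
        assert list(assign_zones(tr, ot_arena)) == ["center", "center"]

    def test_ot_radius_17_is_periphery(self, ot_arena):
        """17.0 mm from center exceeds 17.5*sqrt(0.8) ~ 15.65 mm."""
        assert 17.0 > 17.5 * math.sqrt(0.8)
        tr = Track("s", "x", [0.0, 0.1], [17.5 + 17.0, 17.5 - 17.0],
                   [17.5, 17.5])
        assert list(assign_zones(tr, ot_arena)) == ["periphery", "periphery"]

    def test_shared_edge_goes_to_first_declared_zone(self):
        """Declaration order breaks boundary ties."""
        arena = ArenaSpec(
            "pair",
            [Zone("center", "rectangle", (0, 0, 1, 1)),
             Zone("shallow_1", "rectangle", (1, 0, 2, 1))],
            {frozenset(("center", "shallow_1"))},
        )
        tr = Track("s", "x", [0.0, 0.1], [1.0, 1.0], [0.5, 0.5])
        assert list(assign_zones(tr, arena)) == ["center", "center"]

    def test_outside_samples_warn_and_get_none(self, ot_arena):
        tr = Track("s", "x", [0.0, 0.1], [100.0, 17.5], [100.0, 17.5])
        with pytest.warns(UserWarning, match="bounding box"):
            labels = assign_zones(tr, ot_arena)
        assert list(labels) == ["none", "center"]


class TestExtractVisits:
    def test_no_merging_at_zero_threshold(self):
        track, labels = track_from_labels([("A", 2), ("B", 3), ("A", 2)])
        seq = extract_visits(track, labels, min_dwell=0.0)
        assert seq.zone_sequence() == ["A", "B", "A"]
        assert seq.visits[0].duration == pytest.approx(2.0)
        assert seq.visits[1].duration == pytest.approx(3.0)

    def test_subthreshold_run_merges_into_flanks(self):
        """A 0.1 s blip between two A-visits coalesces into one visit."""
        track, labels = track_from_labels([("A", 2), ("B", 0.1), ("A", 2)])
        seq = extract_visits(track, labels, min_dwell=0.2)
        assert seq.zone_sequence() == ["A"]
        assert seq.visits[0].duration == pytest.approx(4.1)

    def test_none_runs_absorbed_into_preceding_visit(self):
        track, labels = track_from_labels([("A", 1), ("none", 0.5), ("B", 1)])
        seq = extract_visits(track, labels, min_dwell=0.0)
        assert seq.zone_sequence() == ["A", "B"]
        assert seq.visits[0].duration == pytest.approx(1.5)
        assert seq.visits[1].duration == pytest.approx(1.0)

    def test_all_none_yields_empty_sequence_with_warning(self):
        track, labels = track_from_labels([("none", 2)])
        with pytest.warns(UserWarning, match="never enters"):
            seq = extract_visits(track, labels, min_dwell=0.0)
        assert len(seq) == 0

    def test_short_run_between_distinct_flanks_joins_preceding(self):
        track, labels = track_from_labels([("A", 2), ("B", 0.1), ("C", 2)])
        seq = extract_visits(track, labels, min_dwell=0.2)
        assert seq.zone_sequence() == ["A", "C"]
        assert seq.visits[0].duration == pytest.approx(2.1)

    @given(
        runs=st.lists(
            st.tuples(st.sampled_from("AB"), st.floats(0.2, 2.0)),
            min_size=1, max_size=8,
        ),
        dwell_lo=st.floats(0.0, 0.3),
        dwell_hi=st.floats(0.3, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_debounce_monotonicity(self, runs, dwell_lo, dwell_hi):
        """A larger de-bounce threshold never yields more visits."""
        track, labels = track_from_labels(runs)
        n_lo = len(extract_visits(track, labels, min_dwell=dwell_lo))
        n_hi = len(extract_visits(track, labels, min_dwell=dwell_hi))
        assert n_hi <= n_lo


class TestSessionMetrics:
    def test_two_zone_bookkeeping(self, make_visits):
        seq = make_visits([("A", 0, 300), ("B", 300, 600)])
        m = session_metrics(seq)
        assert m.per_zone["A"].time_pct == pytest.approx(50.0)
        assert m.per_zone["B"].time_pct == pytest.approx(50.0)
        assert m.per_zone["A"].entries == 1
        assert m.per_zone["B"].entries == 1
        assert m.per_zone["B"].latency_s == pytest.approx(300.0)
        assert not m.per_zone["B"].censored

    def test_unvisited_zone_is_censored(self, make_visits):
        seq = make_visits([("deep_1", 0, 600)], session_length=600)
        m = session_metrics(seq, zone_ids=["deep_1", "shallow_1"])
        z = m.per_zone["shallow_1"]
        assert z.entries == 0
        assert z.latency_s == 600.0
        assert z.censored

    def test_constant_speed_velocity_and_no_immobility(self, make_visits):
        fr = 30.0
        n = int(60 * fr)
        t = np.arange(n) / fr
        track = Track("s1", "sess1", t, 10.0 * t, np.zeros(n), frame_rate=fr)
        seq = make_visits([("A", 0, 60)], session_length=track.duration)
        m = session_metrics(seq, track, speed_thr=1.0, min_immobile=1.0)
        assert m.mean_velocity == pytest.approx(10.0)
        assert m.immobile_episodes == 0

    def test_immobile_episode_detected(self, make_visits):
        fr = 10.0
        t = np.arange(100) / fr
        x = np.where(t < 5, 10.0 * t, 50.0)  # moves 5 s, then freezes 5 s
        track = Track("s1", "sess1", t, x, np.zeros(100), frame_rate=fr)
        seq = make_visits([("A", 0, 10)], session_length=track.duration)
        m = session_metrics(seq, track, speed_thr=1.0, min_immobile=1.0)
        assert m.immobile_episodes == 1

    def test_mismatched_session_raises(self, make_visits):
        seq = make_visits([("A", 0, 10)])
        track = Track("other", "sess1", [0, 1], [0, 1], [0, 1])
        with pytest.raises(ValueError, match="different sessions"):
            session_metrics(seq, track)

    def test_zone_time_conservation_on_simulated_sessions(self):
        """Per-zone times sum to the session length to 1e-9 s."""
        cfg = SimConfig(assay_id="spm", n_subjects=5, seed=11,
                        session_length=300.0)
        seqs, _ = simulate_visits(cfg)
        for seq in seqs:
            m = session_metrics(seq)
            total = sum(z.time_s for z in m.per_zone.values())
            assert total == pytest.approx(seq.session_length, abs=1e-9)

    def test_entry_latency_censoring_consistency(self):
        """Entry count 0 iff latency equals the censored session length."""
        cfg = SimConfig(assay_id="slalom", n_subjects=8, seed=5,
                        session_length=120.0)
        seqs, _ = simulate_visits(cfg)
        zone_ids = [f"chamber_{k}" for k in range(1, 13)]
        for seq in seqs:
            m = session_metrics(seq, zone_ids=zone_ids)
            for z in m.per_zone.values():
                assert (z.entries == 0) == z.censored
                assert (z.entries == 0) == (z.latency_s == seq.session_length)


class TestRoundTrip:
    @staticmethod
    def _frame_resolved_sequence(seq, frame_rate):
        """Generating zone sequence as a frame grid resolves it (visits
        shorter than one frame interval get no sample)."""
        dt = 1.0 / frame_rate
        n_frames = int(round(seq.session_length / dt))
        labels = []
        vi = 0
        for m in range(n_frames):
            t = m * dt
            while vi < len(seq.visits) - 1 and t >= seq.visits[vi].t_exit:
                vi += 1
            labels.append(seq.visits[vi].zone_id)
        collapsed = [labels[0]]
        for lab in labels[1:]:
            if lab != collapsed[-1]:
                collapsed.append(lab)
        return collapsed

    def test_rendered_track_recovers_generating_visits(self, spm_arena):
        """assign_zones + extract_visits invert the renderer at min_dwell 0."""
        cfg = SimConfig(assay_id="spm", n_subjects=3, seed=21,
                        session_length=120.0, jitter_sd=0.8)
        seqs, tracks = simulate_visits(cfg, spm_arena, render_tracks=True)
        for seq, track in zip(seqs, tracks):
            with warnings.catch_warnings():
                warnings.simplefilter("error")  # no out-of-zone samples
                rec = visits_from_track(track, spm_arena, min_dwell=0.0)
            expected = self._frame_resolved_sequence(seq, cfg.frame_rate)
            assert rec.zone_sequence() == expected
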