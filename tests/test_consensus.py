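"""Confidence-weighted averaging, thresholding and cleanup of scorer panels."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spindlekit as sk
from spindlekit.consensus import (ConsensusConfig, ScoreTrack, average_scores,
                                  build_group_consensus, leave_one_out_consensus,
                                  rasterize_scorer, threshold_and_clean)
from conftest import assert_intervals_close, make_panel


def track_from_scores(scores, fs=100.0):
    scores = np.asarray(scores, dtype=float)
    return ScoreTrack(scores=scores, viewer_counts=np.ones(scores.size, dtype=int),
                      fs=fs)


class TestRasterize:
    def test_half_open_sample_range(self, one_block_grid):
        panel = make_panel(one_block_grid, {"exp1": [(1.0, 0.5, "high")]})
        weights, viewed = rasterize_scorer(panel.records[0], one_block_grid)
        assert np.all(weights[100:150] == 1.0)
        assert weights[99] == 0.0 and weights[150] == 0.0
        assert viewed.all()

    def test_epoch_overlap_keeps_highest_score(self, one_block_grid):
        # same instant marked high in b0e0 and low in overlapping b0e1
        rec = sk.ScorerRecord(
            scorer_id="exp1", subtype="expert",
            viewed_epochs=frozenset(one_block_grid.epoch_ids),
            events=[sk.ScoredEvent(23.0, 1.0, sk.ConfidenceLevel.HIGH, "b0e0"),
                    sk.ScoredEvent(23.0, 1.0, sk.ConfidenceLevel.LOW, "b0e1")])
        weights, _ = rasterize_scorer(rec, one_block_grid)
        assert np.all(weights[2300:2400] == 1.0)

    def test_no_events_all_zero(self, one_block_grid):
        panel = make_panel(one_block_grid, {"exp1": []})
        weights, viewed = rasterize_scorer(panel.records[0], one_block_grid)
        assert np.all(weights == 0.0) and viewed.all()

    def test_unviewed_epochs_flagged(self, one_block_grid):
        rec = sk.ScorerRecord(scorer_id="exp1", subtype="expert",
                              viewed_epochs=frozenset({"b0e0"}), events=[])
        _, viewed = rasterize_scorer(rec, one_block_grid)
        assert viewed[:2500].all()
        assert not viewed[2500:].any()


class TestAverage:
    @pytest.mark.parametrize("n_viewers,weight,expected", [
        (4, 1.0, 0.25),   # 1 of 4 marks high
        (5, 0.5, 0.10),   # 1 of 5 marks low
        (3, 1.0, 1 / 3),
    ])
    def test_single_marker_fraction(self, n_viewers, weight, expected):
        n = 100
        marked = np.zeros(n)
        marked[40:60] = weight
        viewed = np.ones(n, dtype=bool)
        tracks = [(marked, viewed)] + [(np.zeros(n), viewed)] * (n_viewers - 1)
        track = average_scores(tracks, fs=100.0)
        assert track.scores[50] == pytest.approx(expected)
        assert np.all(track.viewer_counts == n_viewers)

    def test_unanimous_high_scores_one(self):
        n = 50
        w = np.zeros(n)
        w[10:30] = 1.0
        viewed = np.ones(n, dtype=bool)
        track = average_scores([(w.copy(), viewed)] * 5, fs=100.0)
        assert np.all(track.scores[10:30] == 1.0)

    def test_denominator_counts_only_viewers(self):
        n = 40
        w1 = np.zeros(n)
        w1[:20] = 1.0
        v1 = np.ones(n, dtype=bool)
        v2 = np.zeros(n, dtype=bool)
        v2[:10] = True  # second scorer only viewed the first 10 samples
        track = average_scores([(w1, v1), (np.zeros(n), v2)], fs=100.0)
        assert np.all(track.scores[:10] == 0.5)    # 2 viewers
        assert np.all(track.scores[10:20] == 1.0)  # 1 viewer
        assert np.all(track.scores[20:] == 0.0)

    def test_zero_viewers_is_score_zero_not_error(self):
        n = 10
        track = average_scores([(np.zeros(n), np.zeros(n, dtype=bool))], fs=100.0)
        assert np.all(track.scores == 0.0)
        assert np.all(track.viewer_counts == 0)


class TestThresholdAndClean:
    def test_merge_short_adjacent(self):
        scores = np.zeros(300)
        scores[100:120] = 0.9   # 0.2 s candidate
        scores[125:150] = 0.9   # gap 0.05 s
        events = threshold_and_clean(track_from_scores(scores), ConsensusConfig(gct=0.5))
        assert len(events) == 1
        ev = events.events[0]
        assert (ev.onset_s, ev.end_s) == (1.0, 1.5)

    def test_min_duration_filter(self):
        scores = np.zeros(300)
        scores[100:125] = 0.9  # isolated 0.25 s
        events = threshold_and_clean(track_from_scores(scores), ConsensusConfig(gct=0.5))
        assert len(events) == 0

    def test_max_duration_filter(self):
        scores = np.zeros(400)
        scores[50:310] = 0.9  # 2.6 s
        events = threshold_and_clean(track_from_scores(scores), ConsensusConfig(gct=0.5))
        assert len(events) == 0

    def test_long_candidates_not_merged(self):
        # both candidates >= 0.3 s: the merge rule requires a short member
        scores = np.zeros(400)
        scores[100:140] = 0.9
        scores[145:185] = 0.9
        events = threshold_and_clean(track_from_scores(scores), ConsensusConfig(gct=0.5))
        assert len(events) == 2

    def test_exceed_is_strict(self):
        scores = np.full(100, 0.5)
        assert len(threshold_and_clean(track_from_scores(scores),
                                       ConsensusConfig(gct=0.5))) == 0

    @given(st.floats(min_value=0.0, max_value=0.94),
           st.floats(min_value=0.01, max_value=0.05))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_gct_monotonicity_of_candidates(self, gct, delta):
        rng = np.random.default_rng(17)
        scores = np.clip(rng.uniform(0, 1, 600), 0, 1)
        track = track_from_scores(scores)
        low = scores > gct
        high = scores > gct + delta
        assert np.all(low[high])  # candidate sets shrink as gct rises


class TestGroupConsensus:
    def test_unanimous_panel_reproduces_input(self, one_block_grid):
        marks = [(1.0, 0.5, "high"), (10.0, 1.2, "high"), (50.0, 0.8, "high")]
        panel = make_panel(one_block_grid, {f"exp{i}": marks for i in range(3)})
        for gct in (0.0, 0.2, 0.5, 0.9, 0.99):
            out = build_group_consensus(panel, "expert", ConsensusConfig(gct=gct))
            assert_intervals_close(out.intervals(), [(m[0], m[1]) for m in marks])

    def test_single_scorer_high_event_survives_gct_04(self, one_block_grid):
        panel = make_panel(one_block_grid, {"exp1": [(5.0, 0.8, "high")]})
        out = build_group_consensus(panel, "expert", ConsensusConfig(gct=0.4))
        assert_intervals_close(out.intervals(), [(5.0, 0.8)])

    def test_high_gct_low_agreement_empty(self, one_block_grid):
        panel = make_panel(one_block_grid,
                           {"exp1": [(5.0, 0.8, "low")],
                            "exp2": [], "exp3": [], "exp4": []})
        # max score 0.5/4 = 0.125 < 0.99
        out = build_group_consensus(panel, "expert", ConsensusConfig(gct=0.99))
        assert len(out) == 0

    def test_empty_panel_rejected(self, one_block_grid):
        panel = make_panel(one_block_grid, {"exp1": []})
        with pytest.raises(ValueError, match="researcher"):
            build_group_consensus(panel, "researcher")

    def test_expert_consensus_is_gold_standard(self, one_block_grid):
        panel = make_panel(one_block_grid, {"exp1": [(5.0, 0.8, "high")]})
        out = build_group_consensus(panel, "expert", ConsensusConfig(gct=0.4))
        assert out.is_gold_standard

    def test_confidence_upgrade_never_removes_samples(self, one_block_grid):
        base = make_panel(one_block_grid, {"exp1": [(5.0, 0.8, "low")],
                                           "exp2": [(5.1, 0.7, "medium")]})
        upgraded = make_panel(one_block_grid, {"exp1": [(5.0, 0.8, "high")],
                                               "exp2": [(5.1, 0.7, "medium")]})
        cfg = ConsensusConfig(gct=0.3)
        tracks = lambda p: [rasterize_scorer(r, one_block_grid) for r in p.records]
        s0 = average_scores(tracks(base), 100.0).scores
        s1 = average_scores(tracks(upgraded), 100.0).scores
        assert np.all((s0 > cfg.gct) <= (s1 > cfg.gct))

    def test_output_durations_within_bounds(self, sim_panel):
        out = build_group_consensus(sim_panel, "expert", ConsensusConfig(gct=0.2))
        assert len(out) > 0
        for ev in out:
            assert 0.3 - 1e-9 <= ev.duration_s <= 2.5 + 1e-9
        # events sorted and non-overlapping
        ivs = out.intervals()
        for (a0, ad), (b0, _) in zip(ivs, ivs[1:]):
            assert b0 >= a0 + ad


class TestLeaveOneOut:
    def test_two_identical_scorers_exclude_one(self, one_block_grid):
        marks = [(2.0, 0.6, "high")]
        panel = make_panel(one_block_grid, {"exp1": marks, "exp2": marks})
        out = leave_one_out_consensus(panel, "exp1", "expert", ConsensusConfig(gct=0.4))
        assert_intervals_close(out.intervals(), [(2.0, 0.6)])
        assert out.n_scorers == 1

    def test_sole_marker_exclusion_drops_event(self, one_block_grid):
        panel = make_panel(one_block_grid,
                           {"exp1": [(2.0, 0.6, "high")],
                            "exp2": [], "exp3": [], "exp4": [], "exp5": []})
        out = leave_one_out_consensus(panel, "exp1", "expert", ConsensusConfig(gct=0.1))
        assert len(out) == 0

    def test_unknown_scorer_rejected(self, one_block_grid):
        panel = make_panel(one_block_grid, {"exp1": [], "exp2": []})
        with pytest.raises(KeyError):
            leave_one_out_consensus(panel, "ghost")

    def test_single_scorer_panel_rejected(self, one_block_grid):
        panel = make_panel(one_block_grid, {"exp1": []})
        with pytest.raises(ValueError, match="single-scorer"):
            leave_one_out_consensus(panel, "exp1")
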