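import numpy as np
import pytest

import spindlekit as sk


@pytest.fixture(scope="session")
def sim_study():
    """Three 115 s blocks of synthetic EEG with ground truth (default regime)."""
    return sk.simulate_eeg(sk.EEGSimConfig(n_blocks=3), seed=11)


@pytest.fixture(scope="session")
def sim_panel(sim_study):
    """Imperfect 10-expert panel over the default synthetic study."""
    _, truth, grid = sim_study
    config = sk.ScorerSimConfig(sensitivity=0.85, jitter_sd_s=0.06,
                                fp_rate_per_min=1.0, confidence_noise=0.2)
    return sk.simulate_panel(truth, grid, n_scorers=10, config=config, seed=12)


@pytest.fixture(scope="session")
def high_snr_study():
    """Strong mid-band bursts on a quiet background, for detector checks."""
    return sk.simulate_eeg(sk.HIGH_SNR_EEG, seed=7)


@pytest.fixture()
def one_block_grid():
    return sk.build_epoch_grid([0.0])


def assert_intervals_close(got, expected, atol=1e-9):
    got, expected = list(got), list(expected)
    assert len(got) == len(expected), f"{len(got)} vs {len(expected)} intervals"
    if got:
        assert np.allclose(np.asarray(got, dtype=float),
                           np.asarray(expected, dtype=float), atol=atol), \
            f"{got} != {expected}"


def make_panel(grid, marks_by_scorer, subtype="expert"):
    """Hand-built AnnotationSet: {scorer: [(onset, dur, confidence), ...]}."""
    records = []
    for scorer_id, marks in marks_by_scorer.items():
        events = []
        for onset, dur, conf in marks:
            ep = next(e.epoch_id for e in grid.epochs if e.contains(onset, dur))
            events.append(sk.ScoredEvent(onset, dur, sk.ConfidenceLevel(conf), ep))
        records.append(sk.ScorerRecord(scorer_id=scorer_id, subtype=subtype,
                                       viewed_epochs=frozenset(grid.epoch_ids),
                                       events=events))
    return sk.AnnotationSet(subject_id="t1", grid=grid, records=records)
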