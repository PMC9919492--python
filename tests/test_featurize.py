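"""Feature encoding, outcome labels and instance building vs enumeration."""

import numpy as np
import pandas as pd
import pytest

from walkcast.featurize import (
    N_FEATURES,
    N_LAGS,
    TEMPORAL_WIDTH,
    InstanceSet,
    build_instances,
    encode_history,
    encode_time,
    label_outcome,
)
from walkcast.preprocess import HourState, cohort_hourly_states, detect_bouts, hourly_states
from walkcast.synthetic import load_preset, simulate_cohort

from conftest import make_series


def states_series(codes, start="2015-08-03"):
    idx = pd.date_range(start, periods=len(codes), freq="h")
    return pd.Series(np.asarray(codes, dtype=np.int8), index=idx, name="P000")


I, A, M = int(HourState.INACTIVE), int(HourState.ACTIVE), int(HourState.MISSING)


class TestEncodeTime:
    def test_monday_afternoon_calendar_lookup(self):
        vec = encode_time(pd.Timestamp("2015-08-03 14:00"))  # a Monday in August
        assert vec.sum() == 4
        hot = set(np.nonzero(vec)[0])
        assert hot == {14, 24 + 0, 31 + 7, 43 + 2}  # hour 14, Mon, Aug, day 3

    def test_exactly_four_ones_any_anchor(self):
        rng = np.random.default_rng(0)
        anchors = pd.Timestamp("2015-01-01") + pd.to_timedelta(
            rng.integers(0, 24 * 700, 50), unit="h"
        )
        for a in anchors:
            assert encode_time(a).sum() == 4

    def test_24h_shift_preserves_hour_block(self):
        a = pd.Timestamp("2015-08-03 09:00")
        va, vb = encode_time(a), encode_time(a + pd.Timedelta(hours=24))
        assert (va[:24] == vb[:24]).all()
        assert not (va[24:31] == vb[24:31]).all()


class TestEncodeHistory:
    def test_span_start_is_all_missing(self):
        s = states_series([I] * 48)
        vec = encode_history(s, s.index[0])
        triples = vec.reshape(N_LAGS, 3)
        assert (triples[:, M] == 1).all()
        assert vec.sum() == N_LAGS

    def test_fully_inactive_recorded_history(self):
        s = states_series([I] * (N_LAGS + 5))
        vec = encode_history(s, s.index[N_LAGS])
        triples = vec.reshape(N_LAGS, 3)
        assert (triples[:, I] == 1).all()

    def test_lag_index_arithmetic(self):
        """A single ACTIVE hour exactly 840 hours back hits the last triple."""
        codes = [I] * (N_LAGS + 2)
        codes[1] = A  # anchor will sit at index 841, so lag 840 is index 1
        s = states_series(codes)
        vec = encode_history(s, s.index[N_LAGS + 1])
        triples = vec.reshape(N_LAGS, 3)
        assert triples[N_LAGS - 1, A] == 1
        assert triples[:, A].sum() == 1
        # lag 1 (anchor-1) is the first triple
        codes2 = [I] * 10
        codes2[4] = A
        s2 = states_series(codes2)
        t2 = encode_history(s2, s2.index[5]).reshape(N_LAGS, 3)
        assert t2[0, A] == 1


class TestLabelOutcome:
    @pytest.mark.parametrize(
        "window, expected",
        [
            ([I, A, M], 1),
            ([I, I, I], 0),
            ([M, M, M], None),
            ([M, M, I], 0),
            ([A, M, M], 1),
        ],
    )
    def test_merge_rule(self, window, expected):
        s = states_series(window + [I])
        assert label_outcome(s, s.index[0], horizon=3) == expected

    def test_window_past_span_skipped(self):
        s = states_series([I, I, I, I])
        assert label_outcome(s, s.index[2], horizon=3) is None

    def test_bad_horizon(self):
        s = states_series([I, I, I])
        with pytest.raises(ValueError):
            label_outcome(s, s.index[0], horizon=0)


def enumeration_oracle(cohort_states, horizon=3):
    """Per-anchor instance construction through the scalar operations."""
    rows = []
    for pid in sorted(cohort_states):
        s = cohort_states[pid]
        for anchor in s.index:
            label = label_outcome(s, anchor, horizon=horizon)
            if label is None:
                continue
            vec = np.concatenate([encode_time(anchor), encode_history(s, anchor)])
            rows.append((pid, anchor, label, vec))
    return rows


class TestBuildInstances:
    def test_two_recorded_days_no_walks(self):
        steps = {f"2015-08-0{d} 10:00": 10 for d in (3, 4)}
        states = cohort_hourly_states([make_series(steps)])
        iset = build_instances(states, horizon=3)
        assert len(iset) == 46  # 48 hours minus the last 2 anchors
        assert (iset.y == 0).all()

    def test_single_bout_labels_three_anchors(self):
        steps = {f"2015-08-03 10:00": 10, "2015-08-04 10:00": 10}
        steps |= {f"2015-08-03 10:3{m}": 90 for m in range(10)}
        states = cohort_hourly_states([make_series(steps)])
        iset = build_instances(states, horizon=3)
        positives = iset.anchors[iset.y == 1]
        expected = pd.DatetimeIndex(
            [f"2015-08-03 {h:02d}:00" for h in (8, 9, 10)]
        )
        assert positives.equals(expected)

    def test_all_missing_participant_yields_nothing(self):
        s = states_series([M] * 48)
        iset = build_instances({"P000": s})
        assert len(iset) == 0

    def test_844_ones_invariant(self, structured_small):
        _, _, states = structured_small
        iset = build_instances(states)
        assert iset.X.shape[1] == N_FEATURES
        assert (iset.X.sum(axis=1) == 844).all()

    def test_matches_enumeration_oracle_on_random_fixtures(self):
        """Vectorized builder == per-anchor scalar path on 2-5 day cohorts."""
        for seed in range(4):
            n_days = 2 + seed
            cfg = load_preset("default", n_participants=2, n_days=n_days, seed=seed)
            cfg = cfg.replace(missing_day_prob=0.3)
            states = cohort_hourly_states(simulate_cohort(cfg))
            iset = build_instances(states)
            oracle = enumeration_oracle(states)
            assert len(iset) == len(oracle)
            for row, (pid, anchor, label, vec) in zip(range(len(iset)), oracle):
                assert iset.participant_ids[row] == pid
                assert iset.anchors[row] == anchor
                assert iset.y[row] == label
                assert (iset.X[row] == vec).all()

    def test_empty_states_rejected(self):
        with pytest.raises(ValueError):
            build_instances({})

    def test_save_load_round_trip(self, tmp_path, structured_small):
        _, _, states = structured_small
        iset = build_instances({k: states[k] for k in list(states)[:2]})
        iset.save(tmp_path / "instances.npz")
        back = InstanceSet.load(tmp_path / "instances.npz")
        assert (back.X == iset.X).all()
        assert (back.y == iset.y).all()
        assert list(back.participant_ids) == list(iset.participant_ids)
        assert back.anchors.equals(iset.anchors)
        assert back.provenance == iset.provenance
        assert (tmp_path / "instances.json").exists()

    def test_duplicate_anchor_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            InstanceSet(
                X=np.zeros((2, N_FEATURES), np.uint8),
                y=np.zeros(2, np.int8),
                participant_ids=np.array(["P0", "P0"], dtype=object),
                anchors=pd.DatetimeIndex(["2015-08-03 00:00"] * 2),
            )
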