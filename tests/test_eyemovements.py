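"""Differentiation, saccade detection against ground truth, trace averaging,
and the outcome-epoch trial-equating control."""

import numpy as np
import pandas as pd
import pytest

from spikeomega import (
    EyeTrace,
    SimConfig,
    average_eye_velocity,
    detect_saccades,
    differentiate_smooth,
    equate_outcome_trials,
    generate_eye_trace,
    generate_session,
    generate_trial_table,
)


def make_trace(x, y=None, blink=None, trial_id=0):
    n = len(x)
    return EyeTrace(
        t_ms=np.arange(n, dtype=float),
        x_deg=np.asarray(x, float),
        y_deg=np.zeros(n) if y is None else np.asarray(y, float),
        blink=np.zeros(n, bool) if blink is None else blink,
        trial_id=trial_id,
    )


class TestDifferentiation:
    def test_linear_ramp_velocity(self):
        t = np.arange(1000) / 1000.0
        d = differentiate_smooth(make_trace(20.0 * t))
        assert np.allclose(d.vx[100:-100], 20.0, atol=0.1)

    def test_constant_position_is_still(self):
        d = differentiate_smooth(make_trace(np.full(500, 3.0)))
        assert np.abs(d.speed).max() < 1e-9
        assert np.abs(d.accel).max() < 1e-9

    def test_quadratic_acceleration(self):
        t = np.arange(2000) / 1000.0
        accel = 120.0  # deg/s^2
        d = differentiate_smooth(make_trace(0.5 * accel * t**2))
        mid = slice(500, 1500)
        assert np.allclose(d.accel[mid], accel, rtol=0.01)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            differentiate_smooth(make_trace(np.zeros(10)))


def inject(x, onset, amp, dur):
    prof = amp * (1 - np.cos(np.pi * np.arange(dur + 1) / dur)) / 2
    x[onset: onset + dur + 1] += prof
    x[onset + dur + 1:] += amp
    return x


class TestDetection:
    def test_single_injected_saccade_found(self):
        x = inject(np.zeros(1500), 700, 4.0, 40)  # peak ~157 deg/s
        events = detect_saccades(make_trace(x), context="fixation")
        assert len(events) == 1
        e = events[0]
        assert e.onset_ms <= 740 and e.offset_ms >= 700
        assert e.peak_velocity_deg_s > 100

    def test_steady_pursuit_not_flagged(self):
        t = np.arange(2000) / 1000.0
        v = 20.0 * (1 - np.exp(-t / 0.05))
        x = np.cumsum(v) / 1000.0
        events = detect_saccades(make_trace(x), context="pursuit")
        assert events == []

    def test_rotation_invariance(self):
        x = inject(np.zeros(1200), 500, 3.0, 35)
        base = detect_saccades(make_trace(x), context="fixation")
        th = np.radians(135.0)
        rotated = detect_saccades(
            make_trace(x * np.cos(th), x * np.sin(th)), context="fixation"
        )
        assert len(base) == len(rotated) == 1
        assert base[0].onset_ms == rotated[0].onset_ms
        assert base[0].peak_velocity_deg_s == pytest.approx(
            rotated[0].peak_velocity_deg_s, rel=1e-9
        )

    def test_all_blink_trace_returns_empty(self):
        n = 600
        trace = make_trace(np.zeros(n), blink=np.ones(n, bool))
        assert detect_saccades(trace) == []

    def test_ground_truth_recall_precision(self):
        cfg = SimConfig(n_trials=100, seed=23, catchup_saccade_rate=1.2)
        session = generate_session(SimConfig(n_trials=100, seed=23,
                                             catchup_saccade_rate=1.2),
                                   n_neurons=1, with_eye_traces=True)
        tp = fp = fn = 0
        for trace, truth in zip(session.eye_traces, session.saccade_truth):
            det = detect_saccades(trace, context="pursuit")
            matched = set()
            for e in det:
                hits = [i for i, s in enumerate(truth)
                        if e.onset_ms <= s.offset_ms and e.offset_ms >= s.onset_ms]
                if hits:
                    matched.update(hits)
                    tp += 1
                else:
                    fp += 1
            fn += len(truth) - len(matched)
        assert fp == 0 and fn == 0 and tp > 50


class TestAveraging:
    def test_identical_clean_traces_pass_through(self):
        t = np.arange(1500) / 1000.0
        x = 20.0 * t
        traces = [make_trace(x.copy(), trial_id=i) for i in range(5)]
        out = average_eye_velocity(traces, [[] for _ in traces], [0.0] * 5)
        assert np.allclose(out[200:-200], 20.0, atol=0.2)

    def test_saccade_interval_uses_remaining_trials(self):
        t = np.arange(1500) / 1000.0
        clean = 20.0 * t
        with_sacc = inject(clean.copy(), 700, 5.0, 40)
        traces = [make_trace(clean.copy()), make_trace(with_sacc, trial_id=1)]
        events = [[], detect_saccades(traces[1], context="pursuit")]
        assert len(events[1]) == 1
        out = average_eye_velocity(traces, events, [0.0, 0.0])
        assert np.allclose(out[650:750], 20.0, atol=0.5)

    def test_pursuit_ensemble_steady_state(self):
        cfg = SimConfig(n_trials=20, seed=31, catchup_saccade_rate=1.0,
                        blink_prob={"delivered": 0.0, "omitted": 0.0},
                        early_saccade_prob={"delivered": 0.0, "omitted": 0.0})
        session = generate_session(cfg, n_neurons=1, with_eye_traces=True)
        table = session.trial_table
        events = [detect_saccades(tr, context="pursuit")
                  for tr in session.eye_traces]
        # align every trial at its motion onset
        offsets = (table["t_motion_ms"] - (table["t_cue_ms"] - 500)).astype(int)
        aligned = []
        for tr, off in zip(session.eye_traces, offsets):
            aligned.append(EyeTrace(tr.t_ms[off:] - off, tr.x_deg[off:],
                                    tr.y_deg[off:], tr.blink[off:], tr.trial_id))
        ev_aligned = []
        for evs, off in zip(events, offsets):
            ev_aligned.append([
                type(e)(e.onset_ms - off, e.offset_ms - off,
                        e.peak_velocity_deg_s, e.trigger, e.trial_id)
                for e in evs
            ])
        out = average_eye_velocity(aligned, ev_aligned,
                                   table["direction_deg"].to_numpy())
        steady = out[400:600]
        assert np.nanmean(np.abs(steady - 20.0)) < 1.0  # within 5 %


class TestEquating:
    def table(self):
        n = 32
        return pd.DataFrame({
            "trial_id": np.arange(n),
            "direction_deg": np.zeros(n),
            "outcome": ["delivered"] * 16 + ["omitted"] * 16,
        })

    def test_nothing_to_do_keeps_all(self):
        t = self.table()
        empty = pd.DataFrame(columns=["trial_id", "onset_ms"])
        kept = equate_outcome_trials(t, empty, empty, seed=0)
        assert len(kept) == 32

    def test_exact_discard_count(self):
        t = self.table()
        sacc = pd.DataFrame({
            "trial_id": list(range(10)) + list(range(16, 22)),
            "onset_ms": [100.0] * 16,
        })
        empty = pd.DataFrame(columns=["trial_id", "onset_ms"])
        kept = equate_outcome_trials(t, sacc, empty, seed=1)
        assert len(kept) == 28  # 4 delivered-with-saccade trials discarded
        kept_sacc = [i for i in kept if i in set(sacc["trial_id"])]
        delivered = sum(i < 16 for i in kept_sacc)
        omitted = sum(i >= 16 for i in kept_sacc)
        assert delivered == omitted == 6

    def test_blink_trials_dropped_first(self):
        t = self.table()
        blink = pd.DataFrame({"trial_id": [0, 20], "onset_ms": [100.0, 499.0]})
        late_blink = pd.DataFrame({"trial_id": [5], "onset_ms": [600.0]})
        empty = pd.DataFrame(columns=["trial_id", "onset_ms"])
        kept = equate_outcome_trials(t, empty, blink, seed=0)
        assert 0 not in kept and 20 not in kept and len(kept) == 30
        kept2 = equate_outcome_trials(t, empty, late_blink, seed=0)
        assert len(kept2) == 32  # blink after the window does not count

    def test_seeded_determinism(self):
        t = self.table()
        sacc = pd.DataFrame({"trial_id": list(range(12)), "onset_ms": [50.0] * 12})
        empty = pd.DataFrame(columns=["trial_id", "onset_ms"])
        a = equate_outcome_trials(t, sacc, empty, seed=7)
        b = equate_outcome_trials(t, sacc, empty, seed=7)
        assert np.array_equal(a, b)

    def test_never_increases_counts_property(self):
        cfg = SimConfig(n_trials=80, seed=41)
        table = generate_trial_table(cfg)
        rng = np.random.default_rng(1)
        sacc = pd.DataFrame({
            "trial_id": rng.choice(80, 30, replace=False),
            "onset_ms": rng.uniform(0, 500, 30),
        })
        empty = pd.DataFrame(columns=["trial_id", "onset_ms"])
        kept = equate_outcome_trials(table, sacc, empty, seed=2)
        assert len(kept) <= 80
        kept_set = set(kept.tolist())
        sub = table[table["trial_id"].isin(kept_set)]
        sacc_set = set(sacc["trial_id"].tolist())
        for _, stratum in sub.groupby("direction_deg"):
            by = stratum.groupby("outcome")["trial_id"].apply(
                lambda ids: sum(i in sacc_set for i in ids)
            )
            if len(by) == 2:
                assert by.iloc[0] == by.iloc[1]
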