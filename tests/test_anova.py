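"""Type II decomposition and partial effect sizes against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from spikeomega import (
    BinnedCounts,
    FactorialDesign,
    SimConfig,
    Type2Solver,
    effectsize_timecourse,
    eta_partial,
    neuron_significance,
    omega_partial,
    omega_partial_epoch,
    simulate_counts,
    generate_trial_table,
    time_varying_flag,
    type2_decomposition,
)


def one_hot_block(levels_per_factor, codes):
    """Kronecker one-hot columns for a term (independent brute-force oracle)."""
    n = len(codes[0])
    block = np.ones((n, 1))
    for levels, code in zip(levels_per_factor, codes):
        ind = np.zeros((n, levels))
        ind[np.arange(n), code] = 1.0
        block = (block[:, :, None] * ind[:, None, :]).reshape(n, -1)
    return block


def brute_force_type2(y, factors):
    """Type II SS by explicit model-comparison over one-hot design matrices."""
    import itertools

    names = list(factors)
    codes = {f: np.unique(v, return_inverse=True)[1] for f, v in factors.items()}
    levels = {f: codes[f].max() + 1 for f in names}
    terms = [t for k in range(1, len(names) + 1)
             for t in itertools.combinations(names, k)]

    def sse(model_terms):
        cols = [np.ones((len(y), 1))]
        cols += [one_hot_block([levels[f] for f in t], [codes[f] for f in t])
                 for t in model_terms]
        X = np.hstack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), int(np.linalg.matrix_rank(X))

    sse_full, rank_full = sse(terms)
    out = {}
    for t in terms:
        reduced = [u for u in terms if not set(t) <= set(u)]
        s0, r0 = sse(reduced)
        s1, r1 = sse(reduced + [t])
        out[t] = (s0 - s1, r1 - r0)
    return out, sse_full, len(y) - rank_full


class TestHandWorkedExample:
    def test_two_group_decomposition(self):
        d = FactorialDesign({"g": np.repeat([0, 1], 3)})
        dec = type2_decomposition(np.array([1, 2, 3, 4, 5, 6.0]), d)
        assert dec.ss[("g",)] == pytest.approx(13.5)
        assert dec.ss_error == pytest.approx(4.0)
        assert dec.df[("g",)] == 1 and dec.df_error == 4
        assert omega_partial(dec, "g") == pytest.approx(12.5 / 18.5)
        assert eta_partial(dec, "g") == pytest.approx(13.5 / 17.5)

    def test_negative_omega_preserved_under_null(self):
        d = FactorialDesign({"g": np.repeat([0, 1], 3)})
        dec = type2_decomposition(np.array([1, 2, 3, 1, 2, 3.0]), d)
        assert omega_partial(dec, "g") == pytest.approx(-0.2)
        assert eta_partial(dec, "g") == pytest.approx(0.0)

    def test_eta_never_below_omega(self, rng):
        d = FactorialDesign({"g": rng.integers(0, 3, 30)})
        for _ in range(20):
            dec = type2_decomposition(rng.normal(size=30), d)
            assert eta_partial(dec, "g") >= omega_partial(dec, "g")


class TestTypeTwoOracles:
    def test_balanced_2x2_equals_sequential(self, rng):
        a = np.repeat([0, 1], 8)
        b = np.tile([0, 1], 8)
        y = rng.normal(size=16)
        dec = type2_decomposition(y, FactorialDesign({"a": a, "b": b}))
        # sequential (Type I) SS on a balanced design equals Type II
        df = pd.DataFrame({"a": a.astype(str), "b": b.astype(str), "y": y})
        tbl = anova_lm(ols("y ~ C(a, Sum)*C(b, Sum)", df).fit(), typ=1)
        assert dec.ss[("a",)] == pytest.approx(tbl.loc["C(a, Sum)", "sum_sq"])
        assert dec.ss[("b",)] == pytest.approx(tbl.loc["C(b, Sum)", "sum_sq"])
        assert dec.ss[("a", "b")] == pytest.approx(
            tbl.loc["C(a, Sum):C(b, Sum)", "sum_sq"]
        )

    def test_unbalanced_2x2_toy_vs_brute_force(self, rng):
        a = np.array([0] * 4 + [1] * 4)
        b = np.array([0, 0, 0, 1, 0, 1, 1, 1])  # cell sizes 3,1,1,3
        y = rng.normal(size=8) + a * 0.7 + b * a
        dec = type2_decomposition(y, FactorialDesign({"a": a, "b": b}))
        oracle, sse_full, df_err = brute_force_type2(y, {"a": a, "b": b})
        for t, (ss, df) in oracle.items():
            assert dec.ss[t] == pytest.approx(ss, abs=1e-10)
            assert dec.df[t] == df
        assert dec.ss_error == pytest.approx(sse_full, abs=1e-10)
        assert dec.df_error == df_err

    def test_statsmodels_type2_agreement_occupied_cells(self, rng):
        la, lc = 3, 4
        base = np.array(np.meshgrid(range(la), range(2), range(lc))).reshape(3, -1).T
        extra = np.column_stack(
            [rng.integers(0, la, 20), rng.integers(0, 2, 20), rng.integers(0, lc, 20)]
        )
        a, b, c = np.vstack([base, extra]).T
        y = rng.normal(size=len(a)) + 0.5 * a + b * (c == 1)
        dec = type2_decomposition(y, FactorialDesign({"a": a, "b": b, "c": c}))
        df = pd.DataFrame(
            {"a": a.astype(str), "b": b.astype(str), "c": c.astype(str), "y": y}
        )
        tbl = anova_lm(ols("y ~ C(a, Sum)*C(b, Sum)*C(c, Sum)", df).fit(), typ=2)
        labels = {
            ("a",): "C(a, Sum)",
            ("b", "c"): "C(b, Sum):C(c, Sum)",
            ("a", "b", "c"): "C(a, Sum):C(b, Sum):C(c, Sum)",
        }
        for t, k in labels.items():
            assert dec.ss[t] == pytest.approx(tbl.loc[k, "sum_sq"], rel=1e-6)

    def test_empty_cell_flags_term_inestimable(self, rng):
        a = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        b = np.array([0, 0, 1, 0, 0, 1, 0, 0])
        b[a == 1] = 0  # cell (1,1) empty
        y = rng.normal(size=8)
        dec = type2_decomposition(y, FactorialDesign({"a": a, "b": b}))
        assert ("a", "b") in dec.inestimable
        assert ("a",) in dec.ss and ("b",) in dec.ss
        with pytest.raises(KeyError):
            dec.term(("a", "b"))


class TestEpochEffectSize:
    def make_binned(self, counts):
        counts = np.asarray(counts)
        return BinnedCounts(
            counts=counts,
            bin_edges_ms=np.arange(counts.shape[1] + 1) * 50.0,
            align_event="cue",
            trial_ids=np.arange(counts.shape[0]),
        )

    def test_constant_in_time_matches_hand_formula(self, rng):
        # counts identical across 2 bins: SS_cond x time == 0, and the epoch
        # value must equal the pooled formula evaluated on hand-computed SS
        z = rng.poisson(8, size=12).astype(float)
        cond = np.repeat([0, 1], 6)
        z[cond == 1] += 5
        binned = self.make_binned(np.column_stack([z, z]))
        design = FactorialDesign({"cond": cond})
        got = omega_partial_epoch(binned, design, "cond")
        dec = Type2Solver(design.with_time(2)).decompose(
            binned.counts.astype(float).ravel()
        )
        ss_t = dec.ss[("cond",)] + dec.ss[("cond", "time")]
        df_t = dec.df[("cond",)] + dec.df[("cond", "time")]
        assert dec.ss[("cond", "time")] == pytest.approx(0.0, abs=1e-9)
        expected = (ss_t - df_t / dec.df_error * dec.ss_error) / (
            ss_t + (dec.n_obs - df_t) / dec.df_error * dec.ss_error
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_pure_temporal_profile_effect_is_positive(self, rng):
        # same marginal mean per condition, opposite temporal profiles
        n = 40
        cond = np.repeat([0, 1], n // 2)
        hi, lo = 12.0, 2.0
        lam = np.where(cond[:, None] == 0, [hi, lo], [lo, hi])
        binned = self.make_binned(rng.poisson(lam))
        design = FactorialDesign({"cond": cond})
        dec = Type2Solver(design.with_time(2)).decompose(
            binned.counts.astype(float).ravel()
        )
        assert dec.ss[("cond", "time")] > 10 * dec.ss[("cond",)]
        assert omega_partial_epoch(binned, design, "cond") > 0.2

    def test_null_epoch_omega_mean_near_zero(self):
        cfg = SimConfig(n_trials=80, baseline_rate_hz=15.0, seed=21)
        table = generate_trial_table(cfg)
        design = FactorialDesign({"cond": table["reward_prob"].to_numpy()})
        solver = Type2Solver(design.with_time(cfg.n_bins))
        rng = np.random.default_rng(5)
        lam = np.full((80, 16), 15.0 * 0.05)
        Y = rng.poisson(lam, size=(200, 80, 16)).reshape(200, -1).T.astype(float)
        vals = []
        for d in solver.decompose_many(Y):
            ss = d.ss[("cond",)] + d.ss[("cond", "time")]
            df = d.df[("cond",)] + d.df[("cond", "time")]
            vals.append(
                (ss - df / d.df_error * d.ss_error)
                / (ss + (d.n_obs - df) / d.df_error * d.ss_error)
            )
        assert abs(np.mean(vals)) < 0.005


class TestTimecourseAndSignificance:
    def test_effect_appears_after_latency(self):
        cfg = SimConfig(
            n_trials=120, baseline_rate_hz=40.0, reward_gain=2.5,
            latency_ms=400, seed=3,
        )
        table = generate_trial_table(cfg)
        counts = simulate_counts(cfg, table, epoch="cue")
        binned = BinnedCounts(counts, np.arange(17) * 50.0, "cue",
                              table["trial_id"].to_numpy())
        design = FactorialDesign({"reward_prob": table["reward_prob"].to_numpy()})
        tc = effectsize_timecourse(binned, design)["reward_prob"]
        early = [r.omega_p2 for r in tc[:8]]
        late = [r.omega_p2 for r in tc[8:]]
        assert max(np.abs(early)) < 0.05  # no information before the latency
        assert min(late) > 0.2

    def test_strong_effect_flagged_and_null_calibrated(self):
        cfg = SimConfig(n_trials=160, baseline_rate_hz=30.0, reward_gain=3.0, seed=9)
        table = generate_trial_table(cfg)
        design = FactorialDesign({"reward_prob": table["reward_prob"].to_numpy()})
        counts = simulate_counts(cfg, table, epoch="cue")
        binned = BinnedCounts(counts, np.arange(17) * 50.0, "cue",
                              table["trial_id"].to_numpy())
        p, flag = neuron_significance(binned, design, "reward_prob")
        assert flag and p < 1e-6

        # null: rejection rate compatible with alpha
        solver = Type2Solver(design.with_time(16))
        rng = np.random.default_rng(17)
        lam = np.full((160, 16), 1.0)
        Y = rng.poisson(lam, size=(400, 160, 16)).reshape(400, -1).T.astype(float)
        rejections = 0
        from scipy import stats as st

        for d in solver.decompose_many(Y):
            ss = d.ss[("reward_prob",)] + d.ss[("reward_prob", "time")]
            df = d.df[("reward_prob",)] + d.df[("reward_prob", "time")]
            f = (ss / df) / (d.ss_error / d.df_error)
            rejections += st.f.sf(f, df, d.df_error) < 0.05
        assert 0.02 <= rejections / 400 <= 0.09

    def test_time_varying_flag(self):
        rng = np.random.default_rng(2)
        table_ids = np.arange(100)
        design = FactorialDesign({"cond": np.repeat([0, 1], 50)})
        ramp = rng.poisson(np.tile(np.linspace(1, 8, 16), (100, 1)))
        flat = rng.poisson(np.full((100, 16), 4.0))
        mk = lambda c: BinnedCounts(c, np.arange(17) * 50.0, "cue", table_ids)
        p_r, f_r = time_varying_flag(mk(ramp), design)
        p_f, f_f = time_varying_flag(mk(flat), design)
        assert f_r and p_r < 1e-10
        assert p_f > 0.01  # well-calibrated most of the time at this seed

    def test_degenerate_identical_counts(self):
        design = FactorialDesign({"cond": np.repeat([0, 1], 10)})
        binned = BinnedCounts(np.full((20, 4), 3), np.arange(5) * 50.0, "cue",
                              np.arange(20))
        with pytest.warns(UserWarning):
            p, flag = neuron_significance(binned, design, "cond")
        assert p == 1.0 and not flag


class TestPartialVsFull:
    def test_second_active_factor_does_not_reduce_first_factor_omega(self):
        # variance explained by the second variable leaves the noise term
        rng = np.random.default_rng(42)
        n = 400
        a = np.tile([0, 1], n // 2)
        b = np.repeat([0, 1, 2, 3], n // 4)
        y = rng.normal(size=n) + a * 1.0 + (b == 2) * 2.0
        d1 = type2_decomposition(y, FactorialDesign({"a": a}, terms=[("a",)]))
        d2 = type2_decomposition(y, FactorialDesign({"a": a, "b": b}))
        assert omega_partial(d2, "a") > omega_partial(d1, "a")
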