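"""Synthetic sessions with the statistical structure of the reward-probability
pursuit/saccade tasks.

A session is a sequence of trials.  Each trial shows a colored cue whose color
signals the probability of reward (low 0.25 / high 0.75), then the target
steps and moves (pursuit) or jumps (saccade) in one of eight directions, and
finally reward is delivered or omitted by a Bernoulli draw at the cued
probability.  Neurons are inhomogeneous Poisson units whose rate within each
task epoch is

    r(t) = baseline * g_reward(condition) * (1 + depth_c * cos(dir - pref))
           * 1[t >= latency]

with the cosine tuning active in the motion epoch, an optional multiplicative
outcome gain in the outcome epoch, and a condition-dependent tuning depth
(``interaction_gain``) that creates a genuine reward x direction interaction.
Eye traces (1 kHz) follow the task kinematics with injected catch-up saccades,
return saccades and blinks, all recorded as ground-truth annotations so that
detection can be scored exactly.

Because spike counts are Poisson, the population (asymptotic) effect size of
every design term is known in closed form from the generating rates
(:func:`population_omega`), which makes estimator bias and parameter-recovery
testable without recorded data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .eyemovements import EyeTrace, SaccadeEvent, BlinkEvent

__all__ = [
    "SimConfig",
    "NeuronData",
    "SessionData",
    "generate_trial_table",
    "generate_spike_train",
    "generate_session",
    "expected_counts",
    "simulate_counts",
    "generate_eye_trace",
    "population_omega",
    "population_omega_mc",
    "reward_gain_for_omega",
    "synthetic_waveform",
    "write_session",
]

DIRECTIONS_DEG = np.arange(0, 360, 45)
EPOCHS = ("cue", "motion", "outcome")


@dataclass
class SimConfig:
    """Generative parameters of one synthetic session.

    Defaults follow the task: reward probabilities 0.25/0.75 signaled at the
    cue, eight directions at 45 degree spacing, 800 ms analysis epochs, 50 ms
    bins, and a median-scale trial count.
    """

    n_trials: int = 160
    reward_probs: tuple[float, float] = (0.25, 0.75)
    n_directions: int = 8
    epoch_duration_ms: int = 800
    bin_ms: int = 50
    baseline_rate_hz: float = 20.0
    reward_gain: float = 1.0
    direction_tuning_depth: float = 0.0
    interaction_gain: float = 0.0
    outcome_gain: float = 1.0
    latency_ms: float = 0.0
    task: str = "pursuit"
    iid_reward_assignment: bool = False
    seed: int = 0
    # behavioral nuisance parameters (trace noise and event frequencies)
    eye_noise_sd_deg: float = 0.005
    pursuit_speed_deg_s: float = 20.0
    catchup_saccade_rate: float = 1.0
    blink_prob: dict = field(
        default_factory=lambda: {"delivered": 0.10, "omitted": 0.15}
    )
    early_saccade_prob: dict = field(
        default_factory=lambda: {"delivered": 0.25, "omitted": 0.15}
    )

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        lo, hi = self.reward_probs
        if not (0 < lo < 1 and 0 < hi < 1):
            raise ValueError("reward probabilities must lie strictly in (0, 1)")
        if self.n_directions <= 0 or self.epoch_duration_ms <= 0 or self.bin_ms <= 0:
            raise ValueError("n_directions, epoch_duration_ms, bin_ms must be positive")
        if self.baseline_rate_hz < 0 or self.latency_ms < 0:
            raise ValueError("baseline_rate_hz and latency_ms must be nonnegative")
        if self.task not in ("pursuit", "saccade"):
            raise ValueError("task must be 'pursuit' or 'saccade'")
        for depth in self._depths():
            if not (0 <= depth <= 1):
                raise ValueError("effective tuning depth must stay in [0, 1]")
        for g in (self.reward_gain, self.outcome_gain):
            if g < 0:
                raise ValueError("gains must be nonnegative (rates stay nonnegative)")

    def _depths(self) -> tuple[float, float]:
        """Effective cosine tuning depth for (low, high) reward conditions."""
        d = self.direction_tuning_depth
        return (d - 0.5 * self.interaction_gain, d + 0.5 * self.interaction_gain)

    @property
    def n_bins(self) -> int:
        if self.epoch_duration_ms % self.bin_ms:
            raise ValueError("epoch_duration_ms must be a multiple of bin_ms")
        return self.epoch_duration_ms // self.bin_ms

    @property
    def directions_deg(self) -> np.ndarray:
        return np.arange(self.n_directions) * (360.0 / self.n_directions)


def _rng(*keys) -> np.random.Generator:
    return np.random.default_rng([int(k) & 0x7FFFFFFF for k in keys])


def generate_trial_table(config: SimConfig, task: str | None = None) -> pd.DataFrame:
    """Draw the factorial realization of one session.

    Reward-probability levels are balanced to within one trial (shuffled
    alternating pairs; set ``iid_reward_assignment`` for i.i.d. draws),
    directions are uniform, and the reward outcome is an independent
    Bernoulli draw at the trial's cued probability.  Event times (cue,
    motion, outcome onset) are on a single session clock in ms.
    """
    task = task or config.task
    rng = _rng(config.seed, 101)
    n = config.n_trials
    lo, hi = config.reward_probs
    if config.iid_reward_assignment:
        is_high = rng.random(n) < 0.5
    else:
        pattern = np.tile([False, True], (n + 1) // 2)[:n]
        is_high = rng.permutation(pattern)
    prob = np.where(is_high, hi, lo)
    direction = config.directions_deg[rng.integers(0, config.n_directions, n)]
    delivered = rng.random(n) < prob

    dur = config.epoch_duration_ms
    t_cue = np.empty(n)
    t_motion = np.empty(n)
    t_outcome = np.empty(n)
    t0 = 0.0
    for i in range(n):
        t_cue[i] = t0 + 500
        t_motion[i] = t_cue[i] + rng.integers(800, 1201)
        t_outcome[i] = t_motion[i] + max(dur, 750) + rng.integers(500, 701)
        t0 = t_outcome[i] + dur + 500
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "task": task,
            "reward_prob": prob,
            "direction_deg": direction,
            "outcome": np.where(delivered, "delivered", "omitted"),
            "t_cue_ms": t_cue,
            "t_motion_ms": t_motion,
            "t_outcome_ms": t_outcome,
        }
    )


def _epoch_rate_ms(
    config: SimConfig,
    epoch: str,
    is_high: bool,
    direction_deg: float,
    delivered: bool,
    preferred_deg: float,
) -> np.ndarray:
    """Per-ms firing rate (Hz) within one 0..epoch_duration epoch."""
    g_reward = config.reward_gain if is_high else 1.0
    rate = config.baseline_rate_hz * g_reward
    if epoch == "motion":
        depth = config._depths()[1 if is_high else 0]
        rate *= 1.0 + depth * math.cos(math.radians(direction_deg - preferred_deg))
    elif epoch == "outcome":
        rate *= config.outcome_gain if delivered else 1.0
    elif epoch != "cue":
        raise ValueError(f"unknown epoch {epoch!r}")
    out = np.full(config.epoch_duration_ms, rate)
    lat = int(round(config.latency_ms))
    if lat > 0:
        out[: min(lat, config.epoch_duration_ms)] = 0.0
    return out


def _trial_rate_ms(config, trial, preferred_deg) -> tuple[np.ndarray, int]:
    """Rate over the whole trial span; returns (per-ms rate, span start in ms)."""
    start = int(trial.t_cue_ms) - 500
    end = int(trial.t_outcome_ms) + config.epoch_duration_ms
    rate = np.full(end - start, config.baseline_rate_hz)
    is_high = trial.reward_prob == max(config.reward_probs)
    delivered = trial.outcome == "delivered"
    for epoch, t_ev in (
        ("cue", trial.t_cue_ms),
        ("motion", trial.t_motion_ms),
        ("outcome", trial.t_outcome_ms),
    ):
        i0 = int(t_ev) - start
        seg = _epoch_rate_ms(
            config, epoch, is_high, trial.direction_deg, delivered, preferred_deg
        )
        rate[i0: i0 + len(seg)] = seg[: len(rate) - i0]
    return rate, start


def generate_spike_train(
    trial, config: SimConfig, preferred_deg: float = 0.0, neuron_id: int = 0
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times (integer ms, session clock) for one trial.

    Counts are drawn per 1 ms bin at the piecewise-constant rate, which is the
    exact Poisson process at the task's 1 ms timestamp resolution.
    Deterministic given (config.seed, neuron_id, trial_id).
    """
    rate, start = _trial_rate_ms(config, trial, preferred_deg)
    if np.any(rate < 0):
        raise ValueError("negative instantaneous rate")
    rng = _rng(config.seed, 211, neuron_id, trial.trial_id)
    counts = rng.poisson(rate / 1000.0)
    return start + np.repeat(np.arange(len(rate)), counts).astype(float)


@dataclass
class NeuronData:
    neuron_id: int
    preferred_direction_deg: float
    spike_times_ms: np.ndarray
    waveform: np.ndarray | None = None
    waveform_fs_hz: float = 40000.0


@dataclass
class SessionData:
    config: SimConfig
    trial_table: pd.DataFrame
    neurons: list[NeuronData]
    eye_traces: list[EyeTrace] | None = None
    saccade_truth: list[list[SaccadeEvent]] | None = None
    blink_truth: list[list[BlinkEvent]] | None = None

    def ground_truth(self) -> dict:
        out = {"per_term_population_omega": {}}
        for epoch in EPOCHS:
            terms = _epoch_factors(epoch)
            for k in range(1, len(terms) + 1):
                import itertools

                for t in itertools.combinations(terms, k):
                    out["per_term_population_omega"][f"{epoch}:{':'.join(t)}"] = (
                        population_omega(self.config, t, epoch=epoch)
                    )
        return out


def generate_session(
    config: SimConfig, n_neurons: int = 1, with_eye_traces: bool = False
) -> SessionData:
    """One trial table shared by ``n_neurons`` simulated units.

    Preferred directions are drawn uniformly from the task's sampled angles,
    so each tuning curve peaks at a tested direction.
    """
    table = generate_trial_table(config)
    rng = _rng(config.seed, 307)
    prefs = config.directions_deg[rng.integers(0, config.n_directions, n_neurons)]
    neurons = []
    for nid in range(n_neurons):
        spikes = np.concatenate(
            [
                generate_spike_train(t, config, prefs[nid], nid)
                for t in table.itertuples()
            ]
        )
        wf = synthetic_waveform(0.2 + 0.5 * rng.random(), rng=rng)
        neurons.append(NeuronData(nid, float(prefs[nid]), np.sort(spikes), wf))
    traces = sacc = blink = None
    if with_eye_traces:
        traces, sacc, blink = [], [], []
        for t in table.itertuples():
            tr, s, b = generate_eye_trace(t, config)
            traces.append(tr)
            sacc.append(s)
            blink.append(b)
    return SessionData(config, table, neurons, traces, sacc, blink)


def expected_counts(
    config: SimConfig,
    trial_table: pd.DataFrame,
    epoch: str = "cue",
    preferred_deg: float = 0.0,
) -> np.ndarray:
    """Expected per-bin spike counts per trial, (n_trials, n_bins)."""
    n_bins = config.n_bins
    lam = np.empty((len(trial_table), n_bins))
    hi = max(config.reward_probs)
    for i, t in enumerate(trial_table.itertuples()):
        r = _epoch_rate_ms(
            config, epoch, t.reward_prob == hi, t.direction_deg,
            t.outcome == "delivered", preferred_deg,
        )
        lam[i] = r.reshape(n_bins, config.bin_ms).sum(axis=1) / 1000.0
    return lam


def simulate_counts(
    config: SimConfig,
    trial_table: pd.DataFrame,
    epoch: str = "cue",
    preferred_deg: float = 0.0,
    neuron_id: int = 0,
) -> np.ndarray:
    """Per-bin Poisson spike counts for one epoch, (n_trials, n_bins).

    Distributionally identical to generating 1 ms spikes and binning them,
    at a fraction of the cost; used by the large replicate studies.
    """
    lam = expected_counts(config, trial_table, epoch, preferred_deg)
    rng = _rng(config.seed, 401, neuron_id)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# eye traces
# ---------------------------------------------------------------------------

def _saccade_profile(amp_deg: float, dur_ms: int) -> np.ndarray:
    """Raised-cosine displacement profile; peak velocity = amp*pi/(2*dur)."""
    t = np.arange(dur_ms + 1) / dur_ms
    return amp_deg * (1 - np.cos(np.pi * t)) / 2


def _inject_saccade(x, y, onset, amp, dur, theta_deg, events):
    prof = _saccade_profile(amp, dur)
    th = math.radians(theta_deg)
    end = min(onset + len(prof), len(x))
    seg = prof[: end - onset]
    x[onset:end] += seg * math.cos(th)
    y[onset:end] += seg * math.sin(th)
    if end < len(x):
        x[end:] += prof[-1] * math.cos(th)
        y[end:] += prof[-1] * math.sin(th)
    peak_v = amp * np.pi / (2 * dur) * 1000.0
    events.append(SaccadeEvent(onset_ms=onset, offset_ms=onset + dur,
                               peak_velocity_deg_s=peak_v, trigger="injected"))


def generate_eye_trace(
    trial, config: SimConfig
) -> tuple[EyeTrace, list[SaccadeEvent], list[BlinkEvent]]:
    """1 kHz gaze trace for one trial with ground-truth event annotations.

    Pursuit trials ramp at the target speed after a ~100 ms latency with
    Poisson-injected catch-up saccades; saccade trials make one main saccade
    to the 10 degree eccentric target.  Return saccades and blinks after the
    outcome occur with outcome-dependent probabilities.  Blink intervals are
    flagged as missing samples, not zeroed.  Times in the annotations are on
    the trial-local clock of the returned trace (t_ms[0] = trial start).
    """
    rng = _rng(config.seed, 503, trial.trial_id)
    start = int(trial.t_cue_ms) - 500
    end = int(trial.t_outcome_ms) + config.epoch_duration_ms
    n = end - start
    x = np.zeros(n)
    y = np.zeros(n)
    saccades: list[SaccadeEvent] = []
    blinks: list[BlinkEvent] = []
    theta = float(trial.direction_deg)
    t_motion = int(trial.t_motion_ms) - start
    t_outcome = int(trial.t_outcome_ms) - start
    motion_dur = 750

    if trial.task == "pursuit":
        lat = int(rng.integers(80, 130))
        onset = t_motion + lat
        # smooth velocity ramp to target speed and smooth stop, time constant 50 ms
        t = np.arange(n - onset)
        v = config.pursuit_speed_deg_s * (1 - np.exp(-t / 50.0)) / 1000.0
        t_stop = motion_dur - lat
        after = t > t_stop
        v[after] = v[min(t_stop, len(v) - 1)] * np.exp(-(t[after] - t_stop) / 50.0)
        disp = np.cumsum(v)
        x[onset:] += disp * math.cos(math.radians(theta))
        y[onset:] += disp * math.sin(math.radians(theta))
        n_catch = rng.poisson(config.catchup_saccade_rate)
        for t_on in sorted(rng.integers(onset + 60, t_motion + motion_dur - 80,
                                        n_catch)):
            _inject_saccade(x, y, int(t_on), float(rng.uniform(1.0, 3.0)),
                            int(rng.integers(25, 46)), theta, saccades)
    else:
        lat = int(rng.integers(160, 240))
        _inject_saccade(x, y, t_motion + lat, 10.0, int(rng.integers(40, 55)),
                        theta, saccades)

    blink_mask = np.zeros(n, dtype=bool)
    b_iv = None
    if rng.random() < config.blink_prob[trial.outcome]:
        b_on = int(rng.integers(t_outcome + 30, t_outcome + 420))
        b_dur = int(rng.integers(80, 200))
        b_iv = (b_on, b_on + b_dur)
        blink_mask[b_on: b_on + b_dur] = True
        blinks.append(BlinkEvent(onset_ms=b_on, offset_ms=min(b_on + b_dur, n)))
    if rng.random() < config.early_saccade_prob[trial.outcome]:
        dur = int(rng.integers(30, 50))
        # keep the return saccade outside the blink: a saccade hidden by a
        # blink is unobservable and would not be a fair detection target
        for _ in range(30):
            t_on = int(rng.integers(t_outcome + 60, t_outcome + 430))
            if b_iv is None or t_on + dur + 25 < b_iv[0] or t_on - 25 > b_iv[1]:
                _inject_saccade(x, y, t_on, float(rng.uniform(3.0, 8.0)), dur,
                                theta + 180.0, saccades)
                break

    x += rng.normal(0, config.eye_noise_sd_deg, n)
    y += rng.normal(0, config.eye_noise_sd_deg, n)
    x[blink_mask] = np.nan
    y[blink_mask] = np.nan
    trace = EyeTrace(
        t_ms=np.arange(n, dtype=float), x_deg=x, y_deg=y, blink=blink_mask,
        trial_id=int(trial.trial_id),
    )
    return trace, saccades, blinks


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

def _epoch_factors(epoch: str) -> tuple[str, ...]:
    if epoch == "cue":
        return ("reward_prob",)
    if epoch == "motion":
        return ("reward_prob", "direction")
    if epoch == "outcome":
        return ("reward_prob", "direction", "outcome")
    raise ValueError(f"unknown epoch {epoch!r}")


def _cell_lambdas(config: SimConfig, epoch: str, preferred_deg: float) -> np.ndarray:
    """Expected per-bin counts for every design cell: shape (*levels, n_bins)."""
    factors = _epoch_factors(epoch)
    shape = {"reward_prob": 2, "direction": config.n_directions, "outcome": 2}
    dims = tuple(shape[f] for f in factors)
    lam = np.zeros(dims + (config.n_bins,))
    for idx in np.ndindex(dims):
        lv = dict(zip(factors, idx))
        r = _epoch_rate_ms(
            config,
            epoch,
            is_high=bool(lv.get("reward_prob", 0)),
            direction_deg=float(config.directions_deg[lv.get("direction", 0)]),
            delivered=bool(lv.get("outcome", 0)),
            preferred_deg=preferred_deg,
        )
        lam[idx] = r.reshape(config.n_bins, config.bin_ms).sum(axis=1) / 1000.0
    return lam


def _term_variance(lam: np.ndarray, factors: tuple[str, ...], term: tuple[str, ...]) -> np.ndarray:
    """Equal-weight factorial variance component of `term`, per bin."""
    import itertools as it

    axes = {f: i for i, f in enumerate(factors)}
    n_fac = len(factors)

    def marginal(subset) -> np.ndarray:
        other = tuple(axes[f] for f in factors if f not in subset)
        m = lam.mean(axis=other, keepdims=True) if other else lam
        return np.broadcast_to(m, lam.shape)

    effect = np.zeros_like(lam)
    for k in range(len(term) + 1):
        for s in it.combinations(term, k):
            effect = effect + (-1) ** (len(term) - k) * marginal(s)
    cell_axes = tuple(range(n_fac))
    return (effect ** 2).mean(axis=cell_axes)


def population_omega(
    config: SimConfig,
    term,
    epoch: str = "cue",
    scope: str = "epoch",
    preferred_deg: float = 0.0,
) -> float | np.ndarray:
    """Population effect size sigma2_effect / (sigma2_effect + sigma2_error).

    sigma2_effect is the equal-weight variance of the term's cell-mean
    contrasts of expected counts; sigma2_error is the mean within-cell count
    variance, which for Poisson counts equals the mean expected count.  With
    ``scope='epoch'`` the per-bin components are pooled by summation — the
    same weighting the whole-epoch estimator applies when it pools a term's
    sum of squares with its time interaction.  Exact for the generator's
    piecewise-constant rates.
    """
    factors = _epoch_factors(epoch)
    term = (term,) if isinstance(term, str) else tuple(term)
    if not set(term) <= set(factors):
        raise ValueError(f"term {term} not in the {epoch}-epoch design {factors}")
    lam = _cell_lambdas(config, epoch, preferred_deg)
    var_eff = _term_variance(lam, factors, term)
    var_err = lam.mean(axis=tuple(range(lam.ndim - 1)))
    if scope == "bin":
        with np.errstate(invalid="ignore"):
            out = np.where(var_eff + var_err > 0, var_eff / (var_eff + var_err), 0.0)
        return out
    num, den = var_eff.sum(), var_eff.sum() + var_err.sum()
    return float(num / den) if den > 0 else 0.0


def population_omega_mc(
    config: SimConfig,
    term,
    epoch: str = "cue",
    n_trials: int = 200_000,
    seed: int = 0,
    preferred_deg: float = 0.0,
) -> float:
    """Monte-Carlo estimate of :func:`population_omega` from simulated counts.

    Draws Poisson counts for every design cell (n_trials split equally) and
    computes the same equal-weight variance components empirically.  Used to
    cross-check the analytic value.
    """
    factors = _epoch_factors(epoch)
    term = (term,) if isinstance(term, str) else tuple(term)
    lam = _cell_lambdas(config, epoch, preferred_deg)
    dims = lam.shape[:-1]
    reps = max(n_trials // int(np.prod(dims)), 2)
    rng = _rng(seed, 601)
    means = np.empty_like(lam)
    wvars = np.empty_like(lam)
    for idx in np.ndindex(dims):
        draws = rng.poisson(lam[idx], size=(reps, lam.shape[-1]))
        means[idx] = draws.mean(axis=0)
        wvars[idx] = draws.var(axis=0, ddof=1)
    var_eff = _term_variance(means, factors, term)
    var_err = wvars.mean(axis=tuple(range(wvars.ndim - 1)))
    num, den = var_eff.sum(), var_eff.sum() + var_err.sum()
    return float(num / den) if den > 0 else 0.0


def reward_gain_for_omega(
    target_omega: float, config: SimConfig, epoch: str = "cue"
) -> float:
    """Reward gain giving a requested population reward effect size.

    Inverts :func:`population_omega` for the two-condition constant-rate
    design by bracketed root finding; gain 1 returns effect 0 exactly.
    """
    if target_omega == 0:
        return 1.0
    if not (0 < target_omega < 1):
        raise ValueError("target effect size must lie in [0, 1)")

    def f(g):
        cfg = SimConfig(**{**asdict(config), "reward_gain": g})
        return population_omega(cfg, "reward_prob", epoch=epoch) - target_omega

    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no gain reaches the requested effect size")
    return float(optimize.brentq(f, 1.0 + 1e-12, hi, xtol=1e-10))


def synthetic_waveform(
    trough_to_peak_ms: float,
    fs_hz: float = 40000.0,
    n_samples: int = 120,
    amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Biphasic extracellular-like waveform: negative trough then positive peak.

    The trough-to-peak separation is the parametric "width"; used to test
    width measurement on a family with known ordering.
    """
    t = (np.arange(n_samples) - n_samples // 3) / fs_hz * 1000.0
    sd1 = max(trough_to_peak_ms / 3.0, 0.03)
    wf = -amplitude * np.exp(-0.5 * (t / sd1) ** 2)
    wf += 0.6 * amplitude * np.exp(-0.5 * ((t - trough_to_peak_ms) / (1.6 * sd1)) ** 2)
    if noise_sd and rng is not None:
        wf = wf + rng.normal(0, noise_sd, n_samples)
    return wf


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_session(session: SessionData, out_dir: str | Path) -> None:
    """Write a session in the package's plain-text layout.

    trials.csv, spikes_<id>.csv (trial_id, spike_time_ms), eye_<id>.csv
    (t_ms, x_deg, y_deg, blink_flag) and ground_truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.trial_table.to_csv(out / "trials.csv", index=False)
    table = session.trial_table
    starts = table["t_cue_ms"].to_numpy() - 500
    ends = table["t_outcome_ms"].to_numpy() + session.config.epoch_duration_ms
    for nrn in session.neurons:
        s = nrn.spike_times_ms
        ids = np.full(len(s), -1)
        for t_id, (a, b) in enumerate(zip(starts, ends)):
            ids[(s >= a) & (s < b)] = t_id
        pd.DataFrame({"trial_id": ids, "spike_time_ms": s}).to_csv(
            out / f"spikes_{nrn.neuron_id}.csv", index=False
        )
    if session.eye_traces:
        for tr in session.eye_traces:
            pd.DataFrame(
                {
                    "t_ms": tr.t_ms,
                    "x_deg": tr.x_deg,
                    "y_deg": tr.y_deg,
                    "blink_flag": tr.blink.astype(int),
                }
            ).to_csv(out / f"eye_{tr.trial_id}.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(session.ground_truth(), fh, indent=1)
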