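"""Neuron-level characterizations: direction tuning, preferred direction,
population tuning alignment, spike-waveform width, and the effect-size
regression on firing rate and waveform width."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .binning import bin_spikes

logger = logging.getLogger(__name__)

__all__ = [
    "TuningCurve",
    "UndefinedPreferredDirectionError",
    "compute_tuning_curve",
    "preferred_direction",
    "align_population_tuning",
    "waveform_width",
    "RegressionResult",
    "rate_width_regression",
]


class UndefinedPreferredDirectionError(ValueError):
    """The rate-weighted vector average has no direction (zero resultant)."""


@dataclass
class TuningCurve:
    directions_deg: np.ndarray
    mean_rate_hz: np.ndarray
    window_ms: tuple[float, float] = (0, 800)


def compute_tuning_curve(
    spike_times_ms,
    trial_table: pd.DataFrame,
    window_ms: tuple[float, float] = (0, 800),
    align_event: str = "motion",
) -> TuningCurve:
    """Mean firing rate per movement direction in a window after motion onset."""
    w0, w1 = window_ms
    binned = bin_spikes(
        spike_times_ms, trial_table, align_event, window_ms, bin_ms=w1 - w0
    )
    totals = binned.counts[:, 0]
    table = trial_table.set_index("trial_id").loc[binned.trial_ids]
    dirs = np.sort(table["direction_deg"].unique())
    rates = np.array(
        [
            totals[table["direction_deg"].to_numpy() == d].mean() / ((w1 - w0) / 1000.0)
            for d in dirs
        ]
    )
    return TuningCurve(directions_deg=dirs, mean_rate_hz=rates, window_ms=window_ms)


def preferred_direction(tc: TuningCurve) -> float:
    """Sampled direction closest to the rate-weighted vector average.

    Ties between equidistant sampled directions break toward the smaller
    angle.  A (near-)zero resultant — e.g. perfectly uniform rates — has no
    direction and raises :class:`UndefinedPreferredDirectionError`.
    """
    r = np.asarray(tc.mean_rate_hz, float)
    if np.all(r <= 0):
        raise UndefinedPreferredDirectionError("no positive rates")
    th = np.radians(tc.directions_deg)
    vx = float(np.sum(r * np.cos(th)))
    vy = float(np.sum(r * np.sin(th)))
    if math.hypot(vx, vy) < 1e-9 * max(r.sum(), 1e-300):
        raise UndefinedPreferredDirectionError("zero resultant vector")
    ang = math.degrees(math.atan2(vy, vx)) % 360.0
    diffs = np.abs((tc.directions_deg - ang + 180.0) % 360.0 - 180.0)
    best = diffs.min()
    candidates = tc.directions_deg[diffs <= best + 1e-9]
    return float(np.min(candidates))


def align_population_tuning(tcs: list[TuningCurve]) -> TuningCurve:
    """Average tuning over relative direction after centering each neuron's
    curve on its preferred direction (which maps to 0 degrees)."""
    aligned = []
    base = None
    for i, tc in enumerate(tcs):
        try:
            pref = preferred_direction(tc)
        except UndefinedPreferredDirectionError:
            logger.warning("neuron %d: undefined preferred direction; excluded", i)
            continue
        dirs = np.sort(np.asarray(tc.directions_deg, float))
        if base is None:
            base = dirs
        rel = (tc.directions_deg - pref) % 360.0
        order = np.argsort(rel)
        aligned.append(np.asarray(tc.mean_rate_hz, float)[order])
    if not aligned:
        raise ValueError("no curves with a defined preferred direction")
    return TuningCurve(
        directions_deg=base, mean_rate_hz=np.mean(aligned, axis=0),
        window_ms=tcs[0].window_ms,
    )


def waveform_width(
    samples: np.ndarray,
    fs_hz: float = 40000.0,
    band_hz: tuple[float, float] | None = (250.0, 6000.0),
) -> float:
    """Trough-to-peak width of a spike waveform, in ms.

    The waveform is band-pass filtered (zero-phase, so the width is not
    biased by filter delay), aligned at its global minimum (trough), and the
    width is the delay to the following global maximum.  A waveform whose
    trough is the last sample has no post-trough peak and is rejected: the
    post-trough convention is deliberate and documented.
    """
    w = np.asarray(samples, float)
    if band_hz is not None:
        sos = signal.butter(2, band_hz, btype="bandpass", fs=fs_hz, output="sos")
        padlen = 3 * (2 * 2 + 1)
        if len(w) <= padlen:
            raise ValueError("waveform shorter than the filter transient")
        w = signal.sosfiltfilt(sos, w)
    trough = int(np.argmin(w))
    if trough >= len(w) - 1:
        raise ValueError("no samples after the trough: width undefined "
                         "(post-trough peak convention)")
    peak = trough + 1 + int(np.argmax(w[trough + 1:]))
    return (peak - trough) / fs_hz * 1000.0


@dataclass
class RegressionResult:
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    p_model: float
    n_used: int


def rate_width_regression(
    rates_hz,
    widths_ms,
    effect_sizes,
    interaction: str = "rate_width",
) -> RegressionResult:
    """OLS fit of effect size on log firing rate, log waveform width, and an
    interaction term.

    ``interaction='rate_width'`` uses log(rate)*log(width);
    ``interaction='rate_rate'`` uses the squared log-rate term instead.
    Observations with nonpositive rate or width are excluded with a warning.
    """
    fr = np.asarray(rates_hz, float)
    ww = np.asarray(widths_ms, float)
    y = np.asarray(effect_sizes, float)
    ok = (fr > 0) & (ww > 0) & np.isfinite(y)
    if not ok.all():
        logger.warning("%d observation(s) with nonpositive rate/width excluded",
                       int((~ok).sum()))
    fr, ww, y = fr[ok], ww[ok], y[ok]
    lf, lw = np.log(fr), np.log(ww)
    if interaction == "rate_width":
        inter, iname = lf * lw, "log_rate:log_width"
    elif interaction == "rate_rate":
        inter, iname = lf * lf, "log_rate:log_rate"
    else:
        raise ValueError("interaction must be 'rate_width' or 'rate_rate'")
    X = np.column_stack([np.ones_like(lf), lf, lw, inter])
    names = ["intercept", "log_rate", "log_width", iname]
    n, k = X.shape
    if n <= k:
        raise ValueError("too few usable observations for the regression")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    df_err = n - k
    mse = sse / df_err
    cov = mse * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_err)
    r2 = 1 - sse / sst if sst > 0 else 0.0
    f = ((sst - sse) / (k - 1)) / mse if mse > 0 else np.inf
    p_model = float(stats.f.sf(f, k - 1, df_err))
    return RegressionResult(
        params=dict(zip(names, beta)),
        bse=dict(zip(names, se)),
        pvalues=dict(zip(names, pvals)),
        r_squared=float(r2),
        p_model=p_model,
        n_used=n,
    )
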