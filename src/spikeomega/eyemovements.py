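"""Eye-movement preprocessing: differentiation, saccade/blink handling, and the
outcome-epoch trial-equating control.

Position traces are sampled at 1 kHz.  Velocity and acceleration are obtained
by differentiating the position after smoothing it with a 5 ms SD Gaussian.
Saccades are threshold events: radial acceleration above 1000 deg/s^2, or
radial speed crossing 15 deg/s during fixation / 50 deg/s while the target
moves on the pursuit task.  Detected intervals are merged across short gaps
and extended outward to where the speed falls back to near the background
level, so the full excision interval is removed when averaging traces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "EyeTrace",
    "SaccadeEvent",
    "BlinkEvent",
    "VelocityTraces",
    "differentiate_smooth",
    "detect_saccades",
    "average_eye_velocity",
    "equate_outcome_trials",
]

ACCEL_THRESHOLD = 1000.0  # deg/s^2
FIXATION_VEL_THRESHOLD = 15.0  # deg/s
PURSUIT_VEL_THRESHOLD = 50.0  # deg/s


@dataclass
class EyeTrace:
    """1 kHz gaze trace; blink samples are flagged (positions may be NaN there)."""

    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    blink: np.ndarray
    trial_id: int = -1


@dataclass
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    peak_velocity_deg_s: float
    trigger: str  # acceleration | fixation_velocity | pursuit_velocity | injected
    trial_id: int = -1


@dataclass
class BlinkEvent:
    onset_ms: float
    offset_ms: float
    trial_id: int = -1


@dataclass
class VelocityTraces:
    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    accel: np.ndarray  # magnitude of the acceleration vector
    valid: np.ndarray  # False where blink (padded) contaminates the derivative


def _fill_blinks(pos: np.ndarray, blink: np.ndarray) -> np.ndarray:
    """Linear interpolation across blink gaps (detection masks them anyway)."""
    out = pos.copy()
    bad = blink | ~np.isfinite(pos)
    if bad.any():
        good = ~bad
        if not good.any():
            return np.zeros_like(pos)
        out[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), pos[good])
    return out


def differentiate_smooth(trace: EyeTrace, smoothing_sd_ms: float = 5.0) -> VelocityTraces:
    """Gaussian-smoothed differentiation of the position signal.

    Positions are smoothed with a Gaussian of the given SD, then velocity and
    acceleration are central differences (units deg/s and deg/s^2).  Samples
    within a blink, padded by the kernel support, are marked invalid.
    """
    n = len(trace.x_deg)
    support = int(math.ceil(4 * smoothing_sd_ms)) + 2
    if n < 2 * support + 3:
        raise ValueError("trace shorter than the smoothing kernel support")
    x = ndimage.gaussian_filter1d(_fill_blinks(trace.x_deg, trace.blink), smoothing_sd_ms)
    y = ndimage.gaussian_filter1d(_fill_blinks(trace.y_deg, trace.blink), smoothing_sd_ms)
    vx = np.gradient(x) * 1000.0
    vy = np.gradient(y) * 1000.0
    ax = np.gradient(vx) * 1000.0
    ay = np.gradient(vy) * 1000.0
    valid = ~ndimage.binary_dilation(trace.blink.astype(bool), iterations=support)
    return VelocityTraces(
        vx=vx, vy=vy, speed=np.hypot(vx, vy), accel=np.hypot(ax, ay), valid=valid
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    d = np.diff(mask.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_saccades(
    trace: EyeTrace,
    context: str = "fixation",
    smoothing_sd_ms: float = 5.0,
    merge_gap_ms: int = 20,
    min_duration_ms: int = 10,
    boundary_speed_deg_s: float | None = None,
) -> list[SaccadeEvent]:
    """Threshold-based saccade detection.

    A sample is saccadic when radial acceleration exceeds 1000 deg/s^2 or
    radial speed crosses the context's velocity criterion (15 deg/s during
    fixation, 50 deg/s during pursuit target motion).  Crossing runs closer
    than ``merge_gap_ms`` are joined, runs shorter than ``min_duration_ms``
    dropped, and event boundaries are extended outward until the speed falls
    below ``boundary_speed_deg_s`` (default 20 for fixation, 30 for pursuit).
    """
    if context not in ("fixation", "pursuit"):
        raise ValueError("context must be 'fixation' or 'pursuit'")
    vel_thr = FIXATION_VEL_THRESHOLD if context == "fixation" else PURSUIT_VEL_THRESHOLD
    if boundary_speed_deg_s is None:
        boundary_speed_deg_s = 20.0 if context == "fixation" else 30.0
    d = differentiate_smooth(trace, smoothing_sd_ms)
    if not d.valid.any():
        logger.warning("trial %d: all samples in blink; no detection", trace.trial_id)
        return []
    hot = ((d.accel > ACCEL_THRESHOLD) | (d.speed > vel_thr)) & d.valid

    runs = _runs(hot)
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] <= merge_gap_ms:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    events = []
    n = len(hot)
    for a, b in merged:
        if b - a < min_duration_ms:
            continue
        while a > 0 and d.speed[a - 1] > boundary_speed_deg_s and d.valid[a - 1]:
            a -= 1
        while b < n and d.speed[b] > boundary_speed_deg_s and d.valid[b]:
            b += 1
        seg = slice(a, b)
        peak = float(np.nanmax(d.speed[seg]))
        if np.any(d.accel[seg] > ACCEL_THRESHOLD):
            trig = "acceleration"
        else:
            trig = "fixation_velocity" if context == "fixation" else "pursuit_velocity"
        events.append(
            SaccadeEvent(
                onset_ms=float(trace.t_ms[a]),
                offset_ms=float(trace.t_ms[min(b, n - 1)]),
                peak_velocity_deg_s=peak,
                trigger=trig,
                trial_id=trace.trial_id,
            )
        )
    return events


def average_eye_velocity(
    traces: list[EyeTrace],
    events: list[list[SaccadeEvent]],
    directions_deg: list[float] | np.ndarray,
    smoothing_sd_ms: float = 20.0,
    align_sample: int = 0,
) -> np.ndarray:
    """Saccade-excised mean eye velocity projected on the target direction.

    Saccade and blink samples are treated as missing; the per-sample average
    uses the remaining trials and is then smoothed with a Gaussian (20 ms SD).
    Samples missing in every trial stay NaN.
    """
    n = min(len(tr.t_ms) for tr in traces) - align_sample
    stack = np.full((len(traces), n), np.nan)
    for i, (tr, evs, theta) in enumerate(zip(traces, events, directions_deg)):
        d = differentiate_smooth(tr)
        proj = d.vx * math.cos(math.radians(theta)) + d.vy * math.sin(math.radians(theta))
        mask = ~d.valid
        for e in evs:
            a = int(e.onset_ms - tr.t_ms[0])
            b = int(e.offset_ms - tr.t_ms[0])
            mask[max(a, 0): min(b + 1, len(mask))] = True
        proj = proj.copy()
        proj[mask] = np.nan
        stack[i] = proj[align_sample: align_sample + n]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    # normalized Gaussian smoothing that ignores missing samples
    finite = np.isfinite(mean)
    filled = np.where(finite, mean, 0.0)
    num = ndimage.gaussian_filter1d(filled, smoothing_sd_ms)
    den = ndimage.gaussian_filter1d(finite.astype(float), smoothing_sd_ms)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-12, num / den, np.nan)
    out[~finite & (den <= 1e-12)] = np.nan
    return out


def equate_outcome_trials(
    trial_table: pd.DataFrame,
    saccade_events: pd.DataFrame,
    blink_events: pd.DataFrame,
    blink_window_ms: float = 500.0,
    saccade_window_ms: float = 500.0,
    seed: int = 0,
) -> np.ndarray:
    """Outcome-epoch behavioral control; returns retained trial ids.

    Drops every trial with a blink starting in the first ``blink_window_ms``
    after the outcome event, then — within each direction stratum — randomly
    discards trials from whichever reward-outcome condition has more trials
    containing an early saccade, until the early-saccade trial counts match.
    Event tables carry trial-local times (ms after the outcome event) in an
    ``onset_ms`` column plus ``trial_id``.
    """
    rng = np.random.default_rng(seed)
    retained = set(trial_table["trial_id"].tolist())
    if len(blink_events):
        early = blink_events[
            (blink_events["onset_ms"] >= 0) & (blink_events["onset_ms"] < blink_window_ms)
        ]
        retained -= set(early["trial_id"].tolist())
    sacc_trials: set = set()
    if len(saccade_events):
        early = saccade_events[
            (saccade_events["onset_ms"] >= 0)
            & (saccade_events["onset_ms"] < saccade_window_ms)
        ]
        sacc_trials = set(early["trial_id"].tolist())

    table = trial_table[trial_table["trial_id"].isin(retained)]
    for direction, stratum in table.groupby("direction_deg"):
        by_outcome = {
            oc: [t for t in grp["trial_id"] if t in sacc_trials]
            for oc, grp in stratum.groupby("outcome")
        }
        if len(by_outcome) < 2:
            logger.warning("direction %s: one outcome condition absent; excluded "
                           "from equating", direction)
            continue
        counts = {oc: len(v) for oc, v in by_outcome.items()}
        lo = min(counts.values())
        for oc, ids in by_outcome.items():
            excess = counts[oc] - lo
            if excess > 0:
                drop = rng.choice(np.array(sorted(ids)), size=excess, replace=False)
                retained -= set(drop.tolist())
    return np.array(sorted(retained))
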