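"""Spike binning and peristimulus time histograms.

Converts spike timestamps (1 ms resolution, session clock) into the two
observables the analysis runs on: per-trial spike counts in fixed-width bins
aligned to a task event (the ANOVA observations) and Gaussian-smoothed PSTHs
(display and decoding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["BinnedCounts", "Psth", "bin_spikes", "compute_psth", "single_trial_rates"]

EVENT_COLUMNS = {"cue": "t_cue_ms", "motion": "t_motion_ms", "outcome": "t_outcome_ms"}


@dataclass
class BinnedCounts:
    """Trials x bins spike-count matrix aligned to one task event."""

    counts: np.ndarray  # (n_trials, n_bins), nonnegative ints
    bin_edges_ms: np.ndarray  # (n_bins + 1,), relative to align event
    align_event: str
    trial_ids: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"bin{j}": self.counts[:, j] for j in range(self.n_bins)}
        return pd.DataFrame({"trial_id": self.trial_ids, **cols})


@dataclass
class Psth:
    """Trial-averaged firing rate at 1 ms resolution (Hz), Gaussian smoothed."""

    t_ms: np.ndarray
    rate_hz: np.ndarray
    align_event: str
    smoothing_sd_ms: float


def _event_times(trial_table: pd.DataFrame, align_event: str) -> tuple[np.ndarray, np.ndarray]:
    col = EVENT_COLUMNS.get(align_event, align_event)
    if col not in trial_table.columns:
        raise ValueError(f"trial table has no event column for {align_event!r}")
    times = trial_table[col].to_numpy(float)
    ok = np.isfinite(times)
    if not ok.all():
        logger.warning(
            "%d trial(s) missing %s event: excluded", int((~ok).sum()), align_event
        )
    return times, ok


def bin_spikes(
    spike_times_ms: np.ndarray,
    trial_table: pd.DataFrame,
    align_event: str = "cue",
    window_ms: tuple[float, float] = (0, 800),
    bin_ms: float = 50,
) -> BinnedCounts:
    """Count spikes in half-open bins ``[edge_j, edge_{j+1})`` after an event.

    Spike and event times must share one clock. Trials whose align event is
    missing (NaN) are dropped with a warning rather than imputed.
    """
    w0, w1 = window_ms
    span = w1 - w0
    n_bins = span / bin_ms
    if span <= 0 or abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("window length must be a positive multiple of bin_ms")
    n_bins = int(round(n_bins))
    spikes = np.sort(np.asarray(spike_times_ms, float))
    times, ok = _event_times(trial_table, align_event)
    trial_ids = trial_table["trial_id"].to_numpy()[ok]
    times = times[ok]
    counts = np.zeros((len(times), n_bins), dtype=int)
    for i, t0 in enumerate(times):
        rel = spikes[np.searchsorted(spikes, t0 + w0): np.searchsorted(spikes, t0 + w1)] - t0
        idx = np.floor((rel - w0) / bin_ms).astype(int)
        # guard against float round-up at the right edge of the window
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts[i] = np.bincount(idx, minlength=n_bins)
    edges = w0 + bin_ms * np.arange(n_bins + 1)
    return BinnedCounts(counts=counts, bin_edges_ms=edges, align_event=align_event,
                        trial_ids=trial_ids)


def _gaussian_kernel(sd_ms: float) -> np.ndarray:
    """FIR Gaussian truncated at +/-5 sd, unit mass, 1 ms steps."""
    half = int(np.ceil(5 * sd_ms))
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / sd_ms) ** 2)
    return k / k.sum()


def _per_ms_counts(
    spike_times_ms, trial_table, align_event, window
) -> tuple[np.ndarray, np.ndarray]:
    w0, w1 = int(window[0]), int(window[1])
    spikes = np.sort(np.asarray(spike_times_ms, float))
    times, ok = _event_times(trial_table, align_event)
    times = times[ok]
    if len(times) == 0:
        raise ValueError("no trials with the requested align event")
    n = w1 - w0
    counts = np.zeros((len(times), n))
    for i, t0 in enumerate(times):
        rel = spikes[np.searchsorted(spikes, t0 + w0): np.searchsorted(spikes, t0 + w1)] - t0
        idx = np.floor(rel - w0).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        counts[i] = np.bincount(idx, minlength=n)
    return counts, times


def compute_psth(
    spike_times_ms: np.ndarray,
    trial_table: pd.DataFrame,
    align_event: str = "cue",
    window_ms: tuple[float, float] = (0, 800),
    smoothing_sd_ms: float = 20.0,
    trim_ms: float = 100.0,
) -> Psth:
    """Trial-averaged rate at 1 ms resolution, Gaussian smoothed.

    The histogram is built on a window extended by ``trim_ms`` on both sides
    and cropped after smoothing, so the displayed interval carries no filter
    edge artifacts (trim_ms must cover the kernel support for that guarantee;
    the default 100 ms equals 5 sd of the default kernel).
    """
    w0, w1 = window_ms
    ext = (w0 - trim_ms, w1 + trim_ms)
    counts, _ = _per_ms_counts(spike_times_ms, trial_table, align_event, ext)
    mean_per_ms = counts.mean(axis=0)
    kernel = _gaussian_kernel(smoothing_sd_ms)
    rate = np.convolve(mean_per_ms, kernel, mode="same") * 1000.0
    t = np.arange(int(ext[0]), int(ext[1]))
    keep = (t >= w0) & (t < w1)
    return Psth(t_ms=t[keep], rate_hz=rate[keep], align_event=align_event,
                smoothing_sd_ms=smoothing_sd_ms)


def single_trial_rates(
    spike_times_ms: np.ndarray,
    trial_table: pd.DataFrame,
    align_event: str = "cue",
    window_ms: tuple[float, float] = (0, 800),
    smoothing_sd_ms: float = 20.0,
    trim_ms: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed single-trial rate traces (Hz): (trials x ms matrix, trial_ids).

    Same kernel, extension and cropping as :func:`compute_psth`, so a class
    average of these rows equals the class PSTH.
    """
    w0, w1 = window_ms
    ext = (w0 - trim_ms, w1 + trim_ms)
    counts, _ = _per_ms_counts(spike_times_ms, trial_table, align_event, ext)
    kernel = _gaussian_kernel(smoothing_sd_ms)
    # symmetric kernel: correlation equals convolution
    sm = ndimage.convolve1d(counts, kernel, axis=1, mode="constant") * 1000.0
    t = np.arange(int(ext[0]), int(ext[1]))
    keep = (t >= w0) & (t < w1)
    _, ok = _event_times(trial_table, align_event)
    return sm[:, keep], trial_table["trial_id"].to_numpy()[ok]
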