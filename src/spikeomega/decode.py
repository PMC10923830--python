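"""Cross-validated nearest-PSTH classification of trial labels.

A deliberately simple decoder used to show that the effect size tracks
decodability: per fold, a template PSTH is computed for every class from the
training trials; each held-out trial's smoothed single-trial rate is assigned
the label of the nearest template in L2 distance over the epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import single_trial_rates

__all__ = ["DecodeResult", "nearest_psth_classify", "nearest_psth_classify_rates"]


@dataclass
class DecodeResult:
    accuracy: float
    n_folds: int
    fold_accuracies: np.ndarray
    fold_sizes: np.ndarray
    seed: int | None


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Per-class shuffled round-robin fold assignment."""
    fold = np.empty(len(labels), dtype=int)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {lab!r} has {len(idx)} trials, fewer than n_folds={n_folds}"
            )
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def nearest_psth_classify_rates(
    rates: np.ndarray,
    labels,
    n_folds: int = 10,
    seed: int | None = None,
) -> DecodeResult:
    """Decode from precomputed single-trial rate traces (trials x time)."""
    rates = np.asarray(rates, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)  # fixed label order; ties break to the first
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(labels, n_folds, rng)
    accs = np.empty(n_folds)
    sizes = np.empty(n_folds, dtype=int)
    for f in range(n_folds):
        test = fold == f
        templates = np.stack(
            [rates[(~test) & (labels == c)].mean(axis=0) for c in classes]
        )
        diff = rates[test][:, None, :] - templates[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        pred = classes[np.argmin(d2, axis=1)]  # argmin ties -> first class
        accs[f] = np.mean(pred == labels[test])
        sizes[f] = int(test.sum())
    acc = float(np.sum(accs * sizes) / sizes.sum())
    return DecodeResult(acc, n_folds, accs, sizes, seed)


def nearest_psth_classify(
    spike_times_ms,
    trial_table: pd.DataFrame,
    label_column: str = "reward_prob",
    align_event: str = "cue",
    window_ms: tuple[float, float] = (0, 800),
    n_folds: int = 10,
    smoothing_sd_ms: float = 20.0,
    seed: int | None = None,
) -> DecodeResult:
    """10-fold cross-validated nearest-PSTH decoding of a trial label.

    Single-trial rates use the same 20 ms Gaussian smoothing and edge-trimmed
    window as the PSTH; folds are stratified by class so no fold loses a
    class at small trial counts.  Templates never include the test trial.
    """
    rates, trial_ids = single_trial_rates(
        spike_times_ms, trial_table, align_event, window_ms, smoothing_sd_ms
    )
    table = trial_table.set_index("trial_id").loc[trial_ids]
    labels = table[label_column].to_numpy()
    return nearest_psth_classify_rates(rates, labels, n_folds, seed)
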