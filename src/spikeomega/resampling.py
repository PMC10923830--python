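"""Across-population inference: Welch statistics with permutation nulls and the
mean-centered bootstrap t test.

Per-neuron effect sizes are non-normal and have population-dependent
variances, so standard ANOVA F tests are avoided.  Instead the
heteroscedasticity-corrected Welch statistics are used as permutation-test
statistics (labels permuted, group sizes preserved), and one-sample questions
use a bootstrap whose null is simulated by resampling the mean-centered
sample.  Monte-Carlo p-values use the add-one correction
p = (1 + #{extreme}) / (1 + R), which is the standard unbiased-conservative
estimate and avoids p = 0; ``exact=True`` enumerates every labeling instead
(feasible for small samples), where p = #{extreme}/total with the observed
labeling included.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResamplingResult",
    "welch_anova_F",
    "welch_t",
    "permutation_welch_anova",
    "permutation_welch_t",
    "bootstrap_t_test",
]

_TIE_TOL = 1e-12


@dataclass
class ResamplingResult:
    statistic: float
    p_value: float
    n_resamples: int
    seed: int | None
    method: str


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 values")
        if np.var(g) == 0:
            raise ValueError("zero-variance group: Welch statistics undefined")
    return gs


def _welch_F_batch(V: np.ndarray, starts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Welch's one-way F for each row of V; groups are contiguous slices."""
    k = len(sizes)
    means = np.add.reduceat(V, starts, axis=1) / sizes
    sq = np.add.reduceat(V * V, starts, axis=1)
    var = (sq - sizes * means**2) / (sizes - 1)
    var = np.maximum(var, 1e-300)
    w = sizes / var
    W = w.sum(axis=1)
    xbar = (w * means).sum(axis=1) / W
    A = (w * (means - xbar[:, None]) ** 2).sum(axis=1) / (k - 1)
    tmp = ((1 - w / W[:, None]) ** 2 / (sizes - 1)).sum(axis=1)
    B = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
    return A / B


def welch_anova_F(groups) -> float:
    """Welch's (1951) heteroscedasticity-corrected one-way ANOVA F statistic."""
    gs = _check_groups(groups)
    v = np.concatenate(gs)[None, :]
    sizes = np.array([len(g) for g in gs], float)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)
    return float(_welch_F_batch(v, starts, sizes)[0])


def _welch_t_batch(V: np.ndarray, n1: int) -> np.ndarray:
    g1, g2 = V[:, :n1], V[:, n1:]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    se = np.sqrt(v1 / n1 + v2 / g2.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    return np.where(se > 0, t, np.where(m1 == m2, 0.0, np.inf * np.sign(m1 - m2)))


def welch_t(g1, g2) -> float:
    """Welch's unequal-variance two-sample t statistic."""
    gs = _check_groups([g1, g2])
    return float(_welch_t_batch(np.concatenate(gs)[None, :], len(gs[0]))[0])


def _perm_matrix(v: np.ndarray, n_resamples: int, rng: np.random.Generator) -> np.ndarray:
    V = np.tile(v, (n_resamples, 1))
    return rng.permuted(V, axis=1)


def _enumerate_perms(n: int):
    return itertools.permutations(range(n))


def permutation_welch_anova(
    groups, n_resamples: int = 10_000, seed: int | None = None, exact: bool = False
) -> ResamplingResult:
    """Permutation test on Welch's ANOVA F across >=2 groups.

    Labels are permuted uniformly with group sizes preserved; p is the
    probability of a permuted F at least as large as the observed one.
    """
    gs = _check_groups(groups)
    v = np.concatenate(gs)
    sizes = np.array([len(g) for g in gs], float)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)
    f_obs = float(_welch_F_batch(v[None, :], starts, sizes)[0])
    if exact:
        perms = np.array(list(_enumerate_perms(len(v))))
        F = _welch_F_batch(v[perms], starts, sizes)
        p = float(np.mean(F >= f_obs - _TIE_TOL))
        return ResamplingResult(f_obs, p, len(perms), seed, "exact permutation Welch ANOVA")
    rng = np.random.default_rng(seed)
    F = _welch_F_batch(_perm_matrix(v, n_resamples, rng), starts, sizes)
    p = (1 + int(np.sum(F >= f_obs - _TIE_TOL))) / (1 + n_resamples)
    return ResamplingResult(f_obs, p, n_resamples, seed, "permutation Welch ANOVA")


def permutation_welch_t(
    g1, g2, n_resamples: int = 10_000, seed: int | None = None, exact: bool = False
) -> ResamplingResult:
    """Two-tailed permutation test on Welch's t between two groups.

    The p-value is exactly invariant to swapping the two groups: the pair is
    canonically ordered internally (|t| is unaffected) so that the same seed
    draws the same permutations.
    """
    gs = _check_groups([g1, g2])
    t_obs = float(_welch_t_batch(np.concatenate(gs)[None, :], len(gs[0]))[0])
    key = lambda g: (len(g), tuple(g))
    if key(gs[1]) < key(gs[0]):
        gs = [gs[1], gs[0]]
    v = np.concatenate(gs)
    n1 = len(gs[0])
    if exact:
        perms = np.array(list(_enumerate_perms(len(v))))
        T = _welch_t_batch(v[perms], n1)
        p = float(np.mean(np.abs(T) >= abs(t_obs) - _TIE_TOL))
        return ResamplingResult(t_obs, p, len(perms), seed, "exact permutation Welch t")
    rng = np.random.default_rng(seed)
    T = _welch_t_batch(_perm_matrix(v, n_resamples, rng), n1)
    p = (1 + int(np.sum(np.abs(T) >= abs(t_obs) - _TIE_TOL))) / (1 + n_resamples)
    return ResamplingResult(t_obs, p, n_resamples, seed, "permutation Welch t")


def bootstrap_t_test(
    sample, n_resamples: int = 10_000, seed: int | None = None
) -> ResamplingResult:
    """Bootstrap t test of mean = 0 (two-tailed), e.g. on effect sizes or
    paired effect-size differences.

    The null is simulated by subtracting the sample mean and resampling the
    centered sample with replacement; p is the probability of a bootstrap t
    at least as far from 0 as the observed t.
    """
    x = np.asarray(sample, float)
    n = len(x)
    if n < 2 or np.var(x) == 0:
        raise ValueError("sample must have >=2 values and nonzero variance")
    t_obs = x.mean() / (x.std(ddof=1) / np.sqrt(n))
    centered = x - x.mean()
    rng = np.random.default_rng(seed)
    draws = centered[rng.integers(0, n, size=(n_resamples, n))]
    m = draws.mean(axis=1)
    s = draws.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_boot = m / (s / np.sqrt(n))
    # degenerate resamples (all values equal): t is 0 if the mean is 0, else infinite
    t_boot = np.where(s > 0, t_boot, np.where(m == 0, 0.0, np.inf))
    p = (1 + int(np.sum(np.abs(t_boot) >= abs(t_obs) - _TIE_TOL))) / (1 + n_resamples)
    return ResamplingResult(float(t_obs), p, n_resamples, seed, "bootstrap t")
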