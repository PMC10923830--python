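"""Type II ANOVA decomposition and partial effect sizes for spike-count designs.

The analytical core of the package: spike counts in 50 ms bins are treated as
observations of an unbalanced factorial design (reward probability, movement
direction, reward outcome, and optionally time-in-epoch), decomposed with
Type II sums of squares, and summarized per term by the unbiased partial
omega-squared effect size

    omega_p^2 = (SS_T - (df_T/df_err) * SS_err)
                / (SS_T + ((N - df_T)/df_err) * SS_err)

which, unlike partial eta-squared, has null expectation ~0 regardless of the
number of conditions.  For whole-epoch summaries, time is added as a factor
and the term of interest is pooled with its interaction with time:

    omega_p^2 = (SS_T + SS_Txt - ((df_T + df_Txt)/df_err) * SS_err)
                / (SS_T + SS_Txt + ((N - df_T - df_Txt)/df_err) * SS_err)

Negative values are legal and preserved: clipping at zero would reintroduce
the positive bias that the estimator exists to remove.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .binning import BinnedCounts

logger = logging.getLogger(__name__)

Term = tuple[str, ...]

__all__ = [
    "FactorialDesign",
    "AnovaDecomposition",
    "EffectSizeResult",
    "Type2Solver",
    "type2_decomposition",
    "omega_partial",
    "eta_partial",
    "omega_partial_epoch",
    "epoch_omega_from_decomposition",
    "epoch_effect_sizes",
    "effectsize_timecourse",
    "neuron_significance",
    "time_varying_flag",
]

_RANK_TOL = 1e-9


def _all_terms(names: list[str]) -> list[Term]:
    """All main effects and interactions of the named factors, low order first."""
    out: list[Term] = []
    for k in range(1, len(names) + 1):
        out.extend(itertools.combinations(names, k))
    return out


def term_label(term: Term) -> str:
    return ":".join(term)


@dataclass
class FactorialDesign:
    """Per-observation factor levels plus the terms entering the model.

    Parameters
    ----------
    factors
        Mapping from factor name to a length-N sequence of level labels
        (any hashable values; they are integer-coded internally).
    terms
        Model terms as tuples of factor names.  Defaults to all main
        effects and all interactions (the fully crossed model).
    """

    factors: dict[str, np.ndarray]
    terms: list[Term] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.factors = {k: np.asarray(v) for k, v in self.factors.items()}
        lengths = {len(v) for v in self.factors.values()}
        if len(lengths) != 1:
            raise ValueError("all factors must have the same number of observations")
        (self.n_obs,) = lengths
        if not self.terms:
            self.terms = _all_terms(list(self.factors))
        self.terms = [tuple(t) for t in self.terms]
        self.levels: dict[str, np.ndarray] = {}
        self.codes: dict[str, np.ndarray] = {}
        for name, vals in self.factors.items():
            levels, codes = np.unique(vals, return_inverse=True)
            if len(levels) < 2:
                raise ValueError(f"factor {name!r} has fewer than 2 observed levels")
            self.levels[name] = levels
            self.codes[name] = codes

    def with_time(self, n_bins: int) -> "FactorialDesign":
        """Replicate the design across time bins, adding 'time' as a factor.

        Observations are ordered bin-major within trial (trial 0 bins 0..B-1,
        trial 1 bins 0..B-1, ...), matching ``BinnedCounts.counts.ravel()``.
        """
        factors = {
            name: np.repeat(vals, n_bins) for name, vals in self.factors.items()
        }
        factors["time"] = np.tile(np.arange(n_bins), self.n_obs)
        return FactorialDesign(factors)

    def _factor_columns(self, name: str) -> np.ndarray:
        """Sum-to-zero (effect) coding: L-1 columns for an L-level factor."""
        codes = self.codes[name]
        n_levels = len(self.levels[name])
        cols = np.zeros((self.n_obs, n_levels - 1))
        for j in range(n_levels - 1):
            cols[codes == j, j] = 1.0
            cols[codes == n_levels - 1, j] = -1.0
        return cols

    def term_columns(self, term: Term) -> np.ndarray:
        """Design-matrix block for one term (row-wise product of factor codings)."""
        blocks = [self._factor_columns(f) for f in term]
        out = blocks[0]
        for b in blocks[1:]:
            # row-wise Khatri-Rao product
            out = (out[:, :, None] * b[:, None, :]).reshape(self.n_obs, -1)
        return out

    def nominal_df(self, term: Term) -> int:
        df = 1
        for f in term:
            df *= len(self.levels[f]) - 1
        return df


@dataclass
class AnovaDecomposition:
    """Per-term Type II sums of squares plus the full-model error term."""

    ss: dict[Term, float]
    df: dict[Term, int]
    ss_error: float
    df_error: int
    n_obs: int
    inestimable: list[Term] = field(default_factory=list)

    def term(self, term) -> Term:
        term = (term,) if isinstance(term, str) else tuple(term)
        if term not in self.ss:
            if term in self.inestimable:
                raise KeyError(f"term {term_label(term)} is inestimable (empty cells)")
            raise KeyError(f"term {term_label(term)} not in decomposition")
        return term


class Type2Solver:
    """Type II sums of squares by marginality-respecting model comparison.

    For each term T, ``SS_T = SSE(M_-T) - SSE(M_-T + T)`` where ``M_-T``
    contains every model term that does not contain T.  SSE is computed by
    projecting onto an orthonormal basis (SVD, rank-tolerant), so unbalanced
    and even deficient designs are handled; a term whose columns add fewer
    dimensions than its nominal degrees of freedom (empty cells) is flagged
    inestimable and excluded.

    The per-model bases are precomputed, so decomposing many response
    vectors that share one design (e.g. hundreds of neurons recorded on the
    same trial sequence) costs one matrix product each.
    """

    def __init__(self, design: FactorialDesign):
        self.design = design
        self.n_obs = design.n_obs
        blocks = {t: design.term_columns(t) for t in design.terms}
        intercept = np.ones((self.n_obs, 1))

        def basis(terms: tuple[Term, ...]) -> tuple[np.ndarray, int]:
            X = np.hstack([intercept] + [blocks[t] for t in terms])
            u, s, _ = np.linalg.svd(X, full_matrices=False)
            rank = int(np.sum(s > _RANK_TOL * s[0]))
            return np.ascontiguousarray(u[:, :rank]), rank

        self._full_terms = tuple(design.terms)
        self._bases: dict[tuple[Term, ...], tuple[np.ndarray, int]] = {}
        self._bases[self._full_terms] = basis(self._full_terms)
        self._pairs: dict[Term, tuple[tuple[Term, ...], tuple[Term, ...]]] = {}
        self.inestimable: list[Term] = []
        self.df: dict[Term, int] = {}
        for t in design.terms:
            reduced = tuple(u for u in design.terms if not set(t) <= set(u))
            augmented = tuple(list(reduced) + [t])
            for key in (reduced, augmented):
                if key not in self._bases:
                    self._bases[key] = basis(key)
            df_t = self._bases[augmented][1] - self._bases[reduced][1]
            if df_t < design.nominal_df(t):
                self.inestimable.append(t)
                logger.warning(
                    "term %s inestimable (rank %d < nominal df %d); excluded",
                    term_label(t), df_t, design.nominal_df(t),
                )
            else:
                self.df[t] = df_t
                self._pairs[t] = (reduced, augmented)
        rank_full = self._bases[self._full_terms][1]
        self.df_error = self.n_obs - rank_full
        if self.df_error < 0:  # cannot happen: rank <= n_obs
            raise ValueError("model rank exceeds number of observations")

    def decompose(self, y: np.ndarray) -> AnovaDecomposition:
        return self.decompose_many(np.asarray(y, float).reshape(-1, 1))[0]

    def decompose_many(self, Y: np.ndarray) -> list[AnovaDecomposition]:
        """Decompose each column of an (n_obs, n_response) matrix."""
        Y = np.asarray(Y, float)
        if Y.ndim != 2 or Y.shape[0] != self.n_obs:
            raise ValueError(f"expected ({self.n_obs}, k) response matrix")
        total = np.einsum("ij,ij->j", Y, Y)
        constant = Y.var(axis=0) == 0  # intercept fits exactly: SSE is 0, not noise
        sse: dict[tuple[Term, ...], np.ndarray] = {}
        for key, (Q, _rank) in self._bases.items():
            proj = Q.T @ Y
            s = np.maximum(total - np.einsum("ij,ij->j", proj, proj), 0.0)
            s[constant] = 0.0
            sse[key] = s
        sse_full = sse[self._full_terms]
        out = []
        for j in range(Y.shape[1]):
            ss = {
                t: float(max(sse[red][j] - sse[aug][j], 0.0))
                for t, (red, aug) in self._pairs.items()
            }
            out.append(
                AnovaDecomposition(
                    ss=ss,
                    df=dict(self.df),
                    ss_error=float(sse_full[j]),
                    df_error=self.df_error,
                    n_obs=self.n_obs,
                    inestimable=list(self.inestimable),
                )
            )
        return out


def type2_decomposition(y: np.ndarray, design: FactorialDesign) -> AnovaDecomposition:
    """Type II ANOVA decomposition of one observation vector.

    Exact on balanced designs (equals the classical sequential decomposition)
    and well-defined on unbalanced ones; see :class:`Type2Solver`.
    """
    y = np.asarray(y, float)
    if y.shape != (design.n_obs,):
        raise ValueError("response length does not match design")
    if design.n_obs <= sum(design.nominal_df(t) for t in design.terms) + 1:
        # not fatal per se, but the error term may vanish
        logger.debug("few observations relative to model df")
    return Type2Solver(design).decompose(y)


def _omega_from_ss(ss_t: float, df_t: int, ss_err: float, df_err: int, n: int) -> float:
    num = ss_t - (df_t / df_err) * ss_err
    den = ss_t + ((n - df_t) / df_err) * ss_err
    if den <= 0:
        warnings.warn("zero-variance response: omega_p^2 undefined, returning 0")
        return 0.0
    return num / den


def omega_partial(decomp: AnovaDecomposition, term) -> float:
    """Unbiased partial omega-squared for one term; may be negative."""
    t = decomp.term(term)
    if decomp.df_error <= 0:
        raise ValueError("df_error must be positive")
    return _omega_from_ss(
        decomp.ss[t], decomp.df[t], decomp.ss_error, decomp.df_error, decomp.n_obs
    )


def eta_partial(decomp: AnovaDecomposition, term) -> float:
    """Partial eta-squared SS_T / (SS_T + SS_err): biased, in [0, 1]."""
    t = decomp.term(term)
    den = decomp.ss[t] + decomp.ss_error
    if den <= 0:
        warnings.warn("zero-variance response: eta_p^2 undefined, returning 0")
        return 0.0
    return decomp.ss[t] / den


def _pooled_term_ss(decomp: AnovaDecomposition, term: Term) -> tuple[float, int]:
    """SS and df of a term pooled with its interaction with time."""
    t = decomp.term(term)
    t_time = tuple(list(t) + ["time"])
    ss, df = decomp.ss[t], decomp.df[t]
    if t_time in decomp.ss:
        ss += decomp.ss[t_time]
        df += decomp.df[t_time]
    return ss, df


def omega_partial_epoch(
    binned: BinnedCounts, design: FactorialDesign, term,
    solver: Type2Solver | None = None,
) -> float:
    """Whole-epoch omega_p^2: term pooled with its time interaction.

    ``design`` describes the per-trial factors; time (one level per bin) and
    all interactions are added internally, and the counts matrix is unravelled
    to trials x bins observations.
    """
    decomp, _ = _epoch_decomposition(binned, design, solver)
    term = (term,) if isinstance(term, str) else tuple(term)
    ss_t, df_t = _pooled_term_ss(decomp, term)
    if decomp.df_error <= 0:
        raise ValueError("df_error must be positive")
    return _omega_from_ss(ss_t, df_t, decomp.ss_error, decomp.df_error, decomp.n_obs)


def epoch_omega_from_decomposition(decomp: AnovaDecomposition, term) -> float:
    """Whole-epoch omega_p^2 from an existing with-time decomposition.

    Useful when one precomputed :class:`Type2Solver` serves many neurons.
    """
    term = (term,) if isinstance(term, str) else tuple(term)
    ss_t, df_t = _pooled_term_ss(decomp, term)
    if decomp.df_error <= 0:
        raise ValueError("df_error must be positive")
    return _omega_from_ss(ss_t, df_t, decomp.ss_error, decomp.df_error, decomp.n_obs)


def _epoch_decomposition(
    binned: BinnedCounts, design: FactorialDesign, solver: Type2Solver | None = None
) -> tuple[AnovaDecomposition, Type2Solver]:
    if design.n_obs != binned.n_trials:
        raise ValueError("design rows do not match binned trial count")
    if solver is None:
        solver = Type2Solver(design.with_time(binned.n_bins))
    y = binned.counts.astype(float).ravel()
    return solver.decompose(y), solver


def epoch_solver(design: FactorialDesign, n_bins: int) -> Type2Solver:
    """Precompute the with-time solver for reuse across neurons sharing a design."""
    return Type2Solver(design.with_time(n_bins))


def epoch_effect_sizes(
    binned: BinnedCounts, design: FactorialDesign,
    solver: Type2Solver | None = None,
) -> dict[str, "EffectSizeResult"]:
    """Whole-epoch omega_p^2 and eta_p^2 for every non-time term."""
    decomp, _ = _epoch_decomposition(binned, design, solver)
    out = {}
    for t in decomp.ss:
        if "time" in t:
            continue
        ss_t, df_t = _pooled_term_ss(decomp, t)
        omega = _omega_from_ss(ss_t, df_t, decomp.ss_error, decomp.df_error, decomp.n_obs)
        den = ss_t + decomp.ss_error
        eta = ss_t / den if den > 0 else 0.0
        out[term_label(t)] = EffectSizeResult(
            term=term_label(t), scope="epoch", omega_p2=omega, eta_p2=eta
        )
    return out


@dataclass
class EffectSizeResult:
    """Effect size of one term, either for one bin or for the whole epoch."""

    term: str
    scope: str  # "epoch" or "bin:<index>"
    omega_p2: float
    eta_p2: float


def effectsize_timecourse(
    binned: BinnedCounts, design: FactorialDesign, terms=None
) -> dict[str, list[EffectSizeResult]]:
    """Per-bin omega_p^2/eta_p^2 time courses (design without a time factor)."""
    if design.n_obs != binned.n_trials:
        raise ValueError("design rows do not match binned trial count")
    solver = Type2Solver(design)
    decomps = solver.decompose_many(binned.counts.astype(float))
    if terms is None:
        wanted = list(solver.df)
    else:
        wanted = [(t,) if isinstance(t, str) else tuple(t) for t in terms]
    out: dict[str, list[EffectSizeResult]] = {term_label(t): [] for t in wanted}
    for j, d in enumerate(decomps):
        for t in wanted:
            out[term_label(t)].append(
                EffectSizeResult(
                    term=term_label(t),
                    scope=f"bin:{j}",
                    omega_p2=omega_partial(d, t),
                    eta_p2=eta_partial(d, t),
                )
            )
    return out


def neuron_significance(
    binned: BinnedCounts, design: FactorialDesign, term, alpha: float = 0.05,
    solver: Type2Solver | None = None,
) -> tuple[float, bool]:
    """Combined F test of a variable's main effect and its time interaction.

    The sums of squares and degrees of freedom of the term and of term x time
    are summed; F is referred to the F(df_pooled, df_error) distribution.
    """
    decomp, _ = _epoch_decomposition(binned, design, solver)
    term = (term,) if isinstance(term, str) else tuple(term)
    ss_t, df_t = _pooled_term_ss(decomp, term)
    if decomp.df_error <= 0:
        raise ValueError("df_error is zero; the F test is undefined")
    mse = decomp.ss_error / decomp.df_error
    if mse == 0:
        warnings.warn("zero error variance; returning p=1")
        return 1.0, False
    f = (ss_t / df_t) / mse
    p = float(stats.f.sf(f, df_t, decomp.df_error))
    return p, p < alpha


def time_varying_flag(
    binned: BinnedCounts, design: FactorialDesign, alpha: float = 0.05,
    solver: Type2Solver | None = None,
) -> tuple[float, bool]:
    """Significance of the time main effect: does the rate vary within the epoch?"""
    decomp, _ = _epoch_decomposition(binned, design, solver)
    t = decomp.term("time")
    if decomp.df_error <= 0:
        raise ValueError("df_error is zero; the F test is undefined")
    mse = decomp.ss_error / decomp.df_error
    if mse == 0:
        warnings.warn("zero error variance; returning p=1")
        return 1.0, False
    f = (decomp.ss[t] / decomp.df[t]) / mse
    p = float(stats.f.sf(f, decomp.df[t], decomp.df_error))
    return p, p < alpha
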