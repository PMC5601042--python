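"""Significance analysis of microarrays (SAM), two-class unpaired.

The per-gene statistic is a regularized relative difference

    d = (mean(treat) - mean(ref)) / (s + s0)

with pooled standard error ``s = sqrt(a * (SS_ref + SS_treat))``,
``a = (1/n1 + 1/n2) / (n1 + n2 - 2)``, and a fudge factor ``s0`` chosen to
stabilize the coefficient of variation of ``d`` across the spread of ``s``.
Significance is assessed against balanced label permutations: observed order
statistics ``d(i)`` are compared with their permutation expectations
``dbar(i)``, a gene is significant at offset ``delta`` when
``|d(i) - dbar(i)| >= delta``, and the FDR at ``delta`` is estimated from the
median number of permuted statistics beyond the least-extreme called values,
scaled by an estimate of the true-null proportion ``pi0``.  A gene's q-value
is the smallest estimated FDR over all deltas at which it is called.

Down-regulation in the treatment (mutant) condition corresponds to d < 0.
The engine is exposed both as a scikit-learn style feature selector
(:class:`SamTwoClassDE`) and as the :func:`call_down_regulated` convenience
wrapper over an :class:`~tapnet.io.ExpressionMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .exceptions import ConfigurationError, DomainError, ValidationError
from .io import ExpressionMatrix

MAX_EXACT_PERMUTATIONS = 10_000


# ---------------------------------------------------------------------------
# Statistic


def d_statistic(wt, mut, s0: float):
    """Relative difference d and pooled standard error s.

    ``wt`` and ``mut`` are replicate intensity vectors for one gene (1-d) or
    stacked per-gene rows (2-d, genes x replicates).  Returns ``(d, s)`` as
    scalars for 1-d input, arrays for 2-d.
    """
    wt_arr = np.atleast_2d(np.asarray(wt, dtype=float))
    mut_arr = np.atleast_2d(np.asarray(mut, dtype=float))
    scalar = np.ndim(wt) == 1
    n1, n2 = wt_arr.shape[1], mut_arr.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 replicates")
    if s0 < 0:
        raise DomainError("s0 must be non-negative")
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    ss = ((wt_arr - wt_arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((mut_arr - mut_arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt(a * ss)
    denom = s + s0
    if np.any(denom == 0):
        bad = np.nonzero(denom == 0)[0]
        raise ZeroDivisionError(
            "zero pooled error with s0=0 for gene rows: "
            + ", ".join(map(str, bad[:10]))
        )
    d = (mut_arr.mean(axis=1) - wt_arr.mean(axis=1)) / denom
    if scalar:
        return float(d[0]), float(s[0])
    return d, s


def _window_mad_cv(d: np.ndarray, s: np.ndarray, n_windows: int = 100) -> float:
    """Coefficient of variation of MAD(d) across s-quantile windows."""
    order = np.argsort(s, kind="stable")
    windows = np.array_split(d[order], min(n_windows, d.size))
    mads = np.array(
        [np.median(np.abs(w - np.median(w))) / 0.6745 for w in windows if w.size]
    )
    mean = mads.mean()
    if mean == 0:
        return 0.0
    return float(mads.std() / mean)


def choose_s0(s_values, d_at_candidates: Callable[[float], np.ndarray]) -> float:
    """Pick the fudge factor minimizing the CV of windowed MAD(d).

    Candidates are 0 and the 0,5,...,95th percentiles of ``s``; ties break
    toward the smallest candidate.  Constant ``s`` degenerates to 0.
    """
    s = np.asarray(s_values, dtype=float)
    if s.size < 100:
        warnings.warn(
            f"s0 selection with only {s.size} genes is unstable", stacklevel=2
        )
    if np.ptp(s) == 0:
        warnings.warn("constant s across genes; s0 set to 0", stacklevel=2)
        return 0.0
    candidates = [0.0] + [float(q) for q in np.percentile(s, np.arange(0, 100, 5))]
    best_s0, best_cv = None, np.inf
    for cand in candidates:
        cv = _window_mad_cv(np.asarray(d_at_candidates(cand), dtype=float), s)
        if cv < best_cv:
            best_s0, best_cv = cand, cv
    return float(best_s0)


# ---------------------------------------------------------------------------
# Permutations


def balanced_assignments(
    n_ref: int,
    n_treat: int,
    n_permutations: int | Literal["all"] = "all",
    seed: int = 0,
) -> list[np.ndarray]:
    """Column-index subsets that play the reference role under relabeling.

    ``'all'`` enumerates every C(n_ref+n_treat, n_ref) balanced assignment
    (including the identity); an integer draws that many seeded assignments.
    """
    n = n_ref + n_treat
    if n_permutations == "all":
        total = comb(n, n_ref)
        if total > MAX_EXACT_PERMUTATIONS:
            raise ConfigurationError(
                f"{total} label assignments exceed the exact-enumeration cap; "
                "pass an integer n_permutations"
            )
        return [np.array(ix, dtype=int) for ix in combinations(range(n), n_ref)]
    n_permutations = int(n_permutations)
    if n_permutations < 2:
        raise ConfigurationError("need at least 2 permutations")
    if n_permutations < 10:
        warnings.warn("fewer than 10 permutations gives a coarse null", stacklevel=2)
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(n, size=n_ref, replace=False)) for _ in range(n_permutations)]


def _permutation_d_table(
    data: np.ndarray, n_ref: int, s0: float, assignments: Sequence[np.ndarray]
) -> np.ndarray:
    """Sorted d vectors (one row per permutation) for genes x samples data."""
    n = data.shape[1]
    table = np.empty((len(assignments), data.shape[0]))
    for row, ref_ix in enumerate(assignments):
        treat_ix = np.setdiff1d(np.arange(n), ref_ix)
        d, _ = d_statistic(data[:, ref_ix], data[:, treat_ix], s0)
        table[row] = np.sort(d)
    return table


def permutation_null(
    matrix: ExpressionMatrix,
    s0: float,
    n_permutations: int | Literal["all"] = "all",
    seed: int = 0,
    reference: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected order statistics dbar and the permuted sorted-d table.

    The matrix must hold exactly two conditions; ``reference`` defaults to
    the first condition in column order.
    """
    conditions = matrix.conditions
    if len(conditions) != 2:
        raise ConfigurationError(
            f"expected exactly 2 conditions, got {conditions}"
        )
    ref = reference if reference is not None else conditions[0]
    if ref not in conditions:
        raise ConfigurationError(f"reference condition {ref!r} not in matrix")
    treat = next(c for c in conditions if c != ref)
    cols = matrix.samples_for(ref) + matrix.samples_for(treat)
    data = matrix.values[cols].to_numpy(dtype=float)
    assignments = balanced_assignments(
        len(matrix.samples_for(ref)), len(matrix.samples_for(treat)),
        n_permutations, seed,
    )
    table = _permutation_d_table(data, len(matrix.samples_for(ref)), s0, assignments)
    return table.mean(axis=0), table


# ---------------------------------------------------------------------------
# FDR and q-values


@dataclass(frozen=True)
class FdrResult:
    fdr: float
    cut_up: float
    cut_low: float
    called: np.ndarray  # boolean mask over the sorted gene order
    pi0: float
    n_called: int


def estimate_pi0(d_sorted: np.ndarray, perm_table: np.ndarray) -> float:
    """Null-proportion estimate from the permutation interquartile range."""
    q25, q75 = np.percentile(perm_table, [25.0, 75.0])
    inside = int(np.count_nonzero((d_sorted > q25) & (d_sorted < q75)))
    return min(1.0, inside / (0.5 * d_sorted.size))


def fdr_at_delta(
    d_sorted: np.ndarray,
    dbar: np.ndarray,
    perm_table: np.ndarray,
    delta: float,
) -> FdrResult:
    """Median-based FDR estimate at offset ``delta``.

    Cut points are the least extreme called d in each direction; the called
    set is every gene beyond a cut point.  FDR = pi0 x median permuted count
    beyond the cuts / number called, clamped to [0, 1].
    """
    if delta < 0:
        raise DomainError("delta must be non-negative")
    diff = d_sorted - dbar
    up = diff >= delta
    down = -diff >= delta
    cut_up = float(d_sorted[up].min()) if up.any() else np.inf
    cut_low = float(d_sorted[down].max()) if down.any() else -np.inf
    called = (d_sorted >= cut_up) | (d_sorted <= cut_low)
    n_called = int(called.sum())
    pi0 = estimate_pi0(d_sorted, perm_table)
    if n_called == 0:
        return FdrResult(0.0, cut_up, cut_low, called, pi0, 0)
    beyond = (perm_table >= cut_up).sum(axis=1) + (perm_table <= cut_low).sum(axis=1)
    fdr = float(np.clip(pi0 * np.median(beyond) / n_called, 0.0, 1.0))
    return FdrResult(fdr, cut_up, cut_low, called, pi0, n_called)


def default_delta_grid(d_sorted: np.ndarray, dbar: np.ndarray, n_points: int = 51) -> np.ndarray:
    top = float(np.abs(d_sorted - dbar).max())
    return np.linspace(0.0, top if top > 0 else 1.0, n_points)


def q_values(
    d_sorted: np.ndarray,
    dbar: np.ndarray,
    perm_table: np.ndarray,
    delta_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-gene q: smallest FDR over grid deltas at which the gene is called.

    A gene is called at ``delta`` when its own offset ``|d - dbar|`` reaches
    ``delta``; this keeps q monotone non-increasing in the offset.  Genes
    called at no grid delta get q = 1.
    """
    if delta_grid is None:
        delta_grid = default_delta_grid(d_sorted, dbar)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid.size == 0:
        raise ConfigurationError("delta grid is empty")
    if np.any(np.diff(delta_grid) < 0):
        raise ConfigurationError("delta grid must be non-decreasing")
    fdrs = np.array(
        [fdr_at_delta(d_sorted, dbar, perm_table, dl).fdr for dl in delta_grid]
    )
    prefix_min = np.minimum.accumulate(fdrs)
    offsets = np.abs(d_sorted - dbar)
    idx = np.searchsorted(delta_grid, offsets, side="right") - 1
    q = np.where(idx >= 0, prefix_min[np.clip(idx, 0, None)], 1.0)
    return q


# ---------------------------------------------------------------------------
# Settings, results, estimator


@dataclass
class SamSettings:
    """Run settings mirroring the study's thresholds.

    ``delta=None`` scans the delta grid for the smallest offset whose
    (right-running-minimum) estimated FDR stays below ``fdr_threshold``;
    a fixed ``delta`` reproduces a reported per-mutant cut-off.
    """

    s0_mode: Literal["auto", "fixed"] = "auto"
    s0_value: float | None = None
    n_permutations: int | Literal["all"] = "all"
    delta: float | None = None
    fold_change_threshold: float = 2.0
    fdr_threshold: float = 0.05
    q_threshold: float = 0.05
    log_transform: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta is not None and self.delta <= 0:
            raise ConfigurationError("delta must be positive")
        if self.s0_mode == "fixed" and (self.s0_value is None or self.s0_value < 0):
            raise ConfigurationError("fixed s0 mode requires a non-negative s0_value")
        if not 0 < self.fdr_threshold <= 1 or not 0 < self.q_threshold <= 1:
            raise ConfigurationError("FDR/q thresholds must lie in (0, 1]")
        if self.fold_change_threshold <= 1:
            raise ConfigurationError("fold-change threshold must exceed 1")


@dataclass(frozen=True)
class SamResult:
    gene: str
    d: float
    s: float
    fold_change: float
    q_value: float
    dbar: float


@dataclass(frozen=True)
class DeCallSet:
    """Per-mutant differential-expression result."""

    mutant_label: str
    down_genes: frozenset[str]
    per_gene: tuple[SamResult, ...]
    achieved_fdr: float
    delta: float
    s0: float
    fdr_exceeded: bool


class SamTwoClassDE(SelectorMixin, BaseEstimator):
    """Two-class unpaired SAM as a scikit-learn feature selector.

    ``fit(X, y)`` takes samples x genes intensities and a two-level label
    vector; the selected features (``get_support``/``transform``) are the
    genes called *down* in the treatment class at the configured delta,
    fold-change and q thresholds.

    Parameters
    ----------
    reference : label of the reference (wild-type) class in ``y``.
    s0 : "auto" for data-driven fudge-factor selection, or a fixed float.
    n_permutations : "all" to enumerate every balanced relabeling, or an int.
    delta : fixed call offset; None scans for the smallest delta whose
        estimated FDR stays below ``fdr_threshold``.
    fold_change_threshold : linear fold change; down calls additionally need
        treat_mean/ref_mean < 1/threshold.
    log_transform : compute the d statistic (and permutation null) on
        log2-transformed intensities, the usual scale for array data; the
        fold change is always the linear-scale mean ratio.  Requires
        strictly positive intensities.
    q_threshold : per-gene q-value ceiling for calls.
    fdr_threshold : run-level FDR target used by the delta scan and the
        ``fdr_exceeded_`` flag.
    n_grid : size of the delta grid for q-values and the delta scan.
    seed : RNG seed for sampled permutations.

    Attributes (after fit)
    ----------------------
    d_, s_, fold_change_, q_values_, dbar_, offset_ : per-gene arrays in
        input column order (``dbar_`` holds the permutation expectation at
        each gene's rank; ``offset_ = d_ - dbar_``).
    s0_, delta_, achieved_fdr_, pi0_, fdr_exceeded_ : run-level scalars.
    support_down_, support_up_ : boolean masks over genes.
    """

    def __init__(
        self,
        reference: str = "wt",
        s0: float | Literal["auto"] = "auto",
        n_permutations: int | Literal["all"] = "all",
        delta: float | None = None,
        fold_change_threshold: float = 2.0,
        q_threshold: float = 0.05,
        fdr_threshold: float = 0.05,
        log_transform: bool = True,
        n_grid: int = 51,
        seed: int = 0,
    ) -> None:
        self.reference = reference
        self.s0 = s0
        self.n_permutations = n_permutations
        self.delta = delta
        self.fold_change_threshold = fold_change_threshold
        self.q_threshold = q_threshold
        self.fdr_threshold = fdr_threshold
        self.log_transform = log_transform
        self.n_grid = n_grid
        self.seed = seed

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=4)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValidationError("y length must match the number of samples")
        labels = list(dict.fromkeys(y.tolist()))
        if len(labels) != 2:
            raise ConfigurationError(f"expected exactly 2 classes, got {labels}")
        if self.reference not in labels:
            raise ConfigurationError(
                f"reference class {self.reference!r} absent from y"
            )
        treat = next(l for l in labels if l != self.reference)
        ref_mask = y == self.reference
        linear = np.concatenate([X[ref_mask].T, X[~ref_mask].T], axis=1)
        n_ref = int(ref_mask.sum())
        n_treat = int((~ref_mask).sum())
        if self.log_transform:
            if np.any(linear <= 0):
                raise ValidationError(
                    "log_transform requires strictly positive intensities"
                )
            data = np.log2(linear)
        else:
            data = linear

        wt = data[:, :n_ref]
        mut = data[:, n_ref:]
        if self.s0 == "auto":
            _, s = d_statistic(wt, mut, 1.0)  # s does not depend on s0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.s0_ = choose_s0(s, lambda cand: d_statistic(wt, mut, cand)[0])
        else:
            self.s0_ = float(self.s0)
        d, s = d_statistic(wt, mut, self.s0_)
        self.d_, self.s_ = d, s
        ref_mean = linear[:, :n_ref].mean(axis=1)
        mut_mean = linear[:, n_ref:].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.fold_change_ = np.where(ref_mean > 0, mut_mean / ref_mean, np.inf)

        assignments = balanced_assignments(
            n_ref, n_treat, self.n_permutations, self.seed
        )
        perm_table = _permutation_d_table(data, n_ref, self.s0_, assignments)
        dbar_sorted = perm_table.mean(axis=0)

        # stable rank of each gene under (d, input position)
        order = np.lexsort((np.arange(d.size), d))
        rank = np.empty_like(order)
        rank[order] = np.arange(d.size)
        self.dbar_ = dbar_sorted[rank]
        self.offset_ = self.d_ - self.dbar_

        d_sorted = d[order]
        grid = default_delta_grid(d_sorted, dbar_sorted, self.n_grid)
        q_sorted = q_values(d_sorted, dbar_sorted, perm_table, grid)
        self.q_values_ = q_sorted[rank]
        self.pi0_ = estimate_pi0(d_sorted, perm_table)

        if self.delta is None:
            self.delta_ = self._scan_delta(d_sorted, dbar_sorted, perm_table, grid)
        else:
            self.delta_ = float(self.delta)
        self.achieved_fdr_ = fdr_at_delta(
            d_sorted, dbar_sorted, perm_table, self.delta_
        ).fdr
        self.fdr_exceeded_ = bool(self.achieved_fdr_ >= self.fdr_threshold)

        fc_down = self.fold_change_ < 1.0 / self.fold_change_threshold
        fc_up = self.fold_change_ > self.fold_change_threshold
        sig_q = self.q_values_ < self.q_threshold
        self.support_down_ = (-self.offset_ >= self.delta_) & fc_down & sig_q
        self.support_up_ = (self.offset_ >= self.delta_) & fc_up & sig_q
        self.treatment_label_ = treat
        return self

    def _scan_delta(self, d_sorted, dbar_sorted, perm_table, grid) -> float:
        fdrs = np.array(
            [fdr_at_delta(d_sorted, dbar_sorted, perm_table, dl).fdr for dl in grid]
        )
        # require the FDR to stay under target for all larger deltas too
        suffix_max = np.maximum.accumulate(fdrs[::-1])[::-1]
        ok = np.nonzero(suffix_max < self.fdr_threshold)[0]
        if ok.size == 0:
            return float(grid[-1]) if grid[-1] > 0 else 1.0
        chosen = float(grid[ok[0]])
        return chosen if chosen > 0 else float(grid[min(ok[0] + 1, grid.size - 1)])

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self)
        return self.support_down_


def call_down_regulated(matrix: ExpressionMatrix, settings: SamSettings,
                        reference: str = "wt") -> DeCallSet:
    """Run SAM on a WT + one-mutant matrix and assemble the down call set."""
    conditions = matrix.conditions
    if len(conditions) != 2:
        raise ConfigurationError(
            f"matrix must hold the reference and exactly one mutant, got {conditions}"
        )
    if reference not in conditions:
        raise ConfigurationError(f"reference condition {reference!r} not in matrix")
    mutant = next(c for c in conditions if c != reference)
    # canonical sample order: replicate order within a condition is
    # statistically irrelevant, and fixing it keeps results bit-identical
    cols = sorted(matrix.samples_for(reference)) + sorted(matrix.samples_for(mutant))
    X = matrix.values[cols].to_numpy(dtype=float).T
    y = np.array([matrix.design[s] for s in cols])
    est = SamTwoClassDE(
        reference=reference,
        s0="auto" if settings.s0_mode == "auto" else settings.s0_value,
        n_permutations=settings.n_permutations,
        delta=settings.delta,
        fold_change_threshold=settings.fold_change_threshold,
        q_threshold=settings.q_threshold,
        fdr_threshold=settings.fdr_threshold,
        log_transform=settings.log_transform,
        seed=settings.seed,
    ).fit(X, y)
    genes = matrix.genes
    per_gene = tuple(
        SamResult(
            gene=g,
            d=float(est.d_[i]),
            s=float(est.s_[i]),
            fold_change=float(est.fold_change_[i]),
            q_value=float(est.q_values_[i]),
            dbar=float(est.dbar_[i]),
        )
        for i, g in enumerate(genes)
    )
    down = frozenset(g for i, g in enumerate(genes) if est.support_down_[i])
    return DeCallSet(
        mutant_label=mutant,
        down_genes=down,
        per_gene=per_gene,
        achieved_fdr=float(est.achieved_fdr_),
        delta=float(est.delta_),
        s0=float(est.s0_),
        fdr_exceeded=bool(est.fdr_exceeded_),
    )
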