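"""The iterative random-forest imputation loop for distance matrices.

Starting from a symmetric column-mean initial guess, the loop fits one
regression forest per incomplete column (ordered by ascending missing
count), writing predictions back immediately so later columns train on
updated values.  Because column-wise imputation breaks symmetry, each
iteration derives a symmetric candidate: either the *split matrix*
procedure (lower-triangle mirror, upper-triangle mirror, elementwise
mean; the winner chosen by least squares, minimum evolution, or the
normalized set difference to the previous iteration) or plain
transpose-mean symmetrization.  Iteration continues while the stop-
criterion error strictly improves and returns the previous iteration's
matrix once it stops improving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .criteria import ls_score, me_score
from .errors import DistanceMatrixError
from .forest import ForestConfig, PriorityTable, fit_forest, predict_forest, priority_table
from .matrix_core import (
    DistanceMatrix,
    column_order,
    initial_guess,
    set_difference_error,
    validate_mask,
)
from .neighbor_joining import PhyloTree, nj_tree, q_matrix

CANDIDATE_STRATEGIES = ("split_three", "symmetrize_each_column", "symmetrize_at_end")
SELECTORS = ("ls", "me", "set_difference")
STOP_CRITERIA = ("ls", "set_difference")


@dataclass
class ImputationConfig:
    """Strategy switches and hyperparameters for one imputation run.

    The default profile is the recommended one: split-matrix candidates
    selected by least squares, random SSR tie-break, LS stop criterion
    ("Split-LS-Rand"), with the tuned non-bootstrap forest.
    """

    forest: ForestConfig = field(default_factory=ForestConfig.non_bootstrap)
    candidate_strategy: str = "split_three"
    selector: str = "ls"
    stop_criterion: str = "ls"
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if self.candidate_strategy not in CANDIDATE_STRATEGIES:
            raise ValueError(f"unknown candidate_strategy {self.candidate_strategy!r}")
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.stop_criterion not in STOP_CRITERIA:
            raise ValueError(f"unknown stop_criterion {self.stop_criterion!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    @classmethod
    def split_ls_rand(cls, seed: int | None = None) -> "ImputationConfig":
        return cls(forest=ForestConfig.non_bootstrap(seed=seed))

    @classmethod
    def bootstrap_profile(cls, seed: int | None = None) -> "ImputationConfig":
        return cls(forest=ForestConfig.bootstrap_profile(seed=seed))


@dataclass
class ImputationResult:
    imputed: DistanceMatrix
    tree: PhyloTree
    iterations: int
    error_trace: list[float]
    config: ImputationConfig
    converged: bool = True


def mean_impute(matrix: DistanceMatrix, mask: np.ndarray) -> DistanceMatrix:
    """Baseline imputer: symmetric column-mean fill only (no forest loop)."""
    return initial_guess(matrix, mask)


def _triangle_candidates(v: np.ndarray) -> list[np.ndarray]:
    lower = np.tril(v, -1)
    upper = np.triu(v, 1)
    return [lower + lower.T, upper + upper.T, 0.5 * (v + v.T)]


def select_candidate(
    m_raw: DistanceMatrix,
    m_prev: DistanceMatrix,
    config: ImputationConfig,
) -> tuple[DistanceMatrix, PhyloTree | None]:
    """Derive the iteration's symmetric matrix from the raw imputed one.

    Under ``split_three`` the lower-mirror, upper-mirror and transpose-mean
    candidates compete; the selector picks the one whose NJ tree fits best
    (``ls``), whose NJ tree is shortest (``me``), or which is closest to
    the previous iteration's matrix (``set_difference``, no tree built).
    The symmetrize-only strategies return the transpose mean directly.
    """
    cand_dm, tree, _ = _select_candidate_scored(m_raw, m_prev, config)
    return cand_dm, tree


def _select_candidate_scored(
    m_raw: DistanceMatrix,
    m_prev: DistanceMatrix,
    config: ImputationConfig,
) -> tuple[DistanceMatrix, PhyloTree | None, float | None]:
    v = m_raw.values
    if config.candidate_strategy != "split_three":
        return DistanceMatrix(m_raw.labels, 0.5 * (v + v.T)), None, None
    cands = [DistanceMatrix(m_raw.labels, c) for c in _triangle_candidates(v)]
    if config.selector == "set_difference":
        scores = [set_difference_error(c, m_prev) for c in cands]
        k = int(np.argmin(scores))
        return cands[k], None, None
    trees = [nj_tree(c) for c in cands]
    if config.selector == "ls":
        scores = [ls_score(c, t) for c, t in zip(cands, trees)]
    else:  # me
        scores = [me_score(t) for t in trees]
    k = int(np.argmin(scores))
    ls_k = scores[k] if config.selector == "ls" else None
    return cands[k], trees[k], ls_k


def stop_error(
    m_curr: DistanceMatrix,
    m_prev: DistanceMatrix,
    tree_curr: PhyloTree | None,
    config: ImputationConfig,
) -> float:
    """Per-iteration error used by the stopping rule.

    ``set_difference`` compares the current matrix cell-by-cell with the
    previous iteration's; ``ls`` scores the current matrix against its own
    NJ tree, so iteration stops when the matrix-to-tree fit stops
    improving (a per-matrix phylogenetic score).
    """
    if config.stop_criterion == "set_difference":
        return set_difference_error(m_curr, m_prev)
    tree = tree_curr if tree_curr is not None else nj_tree(m_curr)
    return ls_score(m_curr, tree)


def _observed_reference(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Symmetry-consistent observed values: one-sided observed pairs are
    mirrored; two-sided observed pairs keep their input values."""
    ref = values.copy()
    one_sided = mask & ~mask.T
    ref[one_sided] = values.T[one_sided]  # copy the observed partner
    return ref


def impute(
    matrix: DistanceMatrix,
    mask: np.ndarray,
    config: ImputationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> ImputationResult:
    """Impute all masked cells of a distance matrix.

    Runs the initial guess, then iterates column-wise forest imputation
    with immediate write-back, candidate symmetrization/selection, and
    the configured stop rule; returns the last strictly-improving
    iteration's matrix together with its NJ tree.  Observed cells are
    re-asserted from the input after every write and are preserved
    exactly in the result.
    """
    config = config or ImputationConfig()
    mask = validate_mask(matrix, mask)
    n = matrix.n
    if n < 4:
        raise DistanceMatrixError("imputation needs N >= 4 OTUs")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.forest.seed if rng is None else rng)

    obs = ~mask
    np.fill_diagonal(obs, True)
    obs_ref = _observed_reference(np.nan_to_num(matrix.values, nan=0.0), mask)

    m0 = initial_guess(matrix, mask)
    order = column_order(mask)
    if order.order.size == 0:
        return ImputationResult(
            imputed=m0, tree=nj_tree(m0), iterations=1, error_trace=[],
            config=config, converged=True,
        )

    priorities: PriorityTable | None = None
    if config.forest.tiebreak == "q_priority":
        priorities = priority_table(q_matrix(m0))

    labels = matrix.labels
    m_new = m0.values.copy()
    prev_vals = m_new.copy()
    prev_tree: PhyloTree | None = None
    old_error = math.inf
    trace: list[float] = []
    converged = False
    iterations = 0

    for it in range(1, config.max_iterations + 1):
        iterations = it
        m_old = m_new.copy()
        for c in order.order:
            miss_rows = mask[:, c].copy()
            obs_rows = ~miss_rows
            obs_rows[c] = False  # the structural diagonal row never trains
            feats = [j for j in range(n) if j != c]
            X = m_new[:, feats]
            forest = fit_forest(
                X[obs_rows], m_new[obs_rows, c], target_col=int(c),
                config=config.forest, priorities=priorities, rng=rng,
                feature_ids=feats,
            )
            m_new[miss_rows, c] = predict_forest(forest, X[miss_rows])
            m_new[obs] = obs_ref[obs]  # re-assert observed values
            if config.candidate_strategy == "symmetrize_each_column":
                m_new = 0.5 * (m_new + m_new.T)
                m_new[obs] = obs_ref[obs]

        cand, tree, cand_ls = _select_candidate_scored(
            DistanceMatrix(labels, m_new), DistanceMatrix(labels, m_old), config
        )
        m_new = cand.values.copy()
        m_new[obs] = obs_ref[obs]
        np.fill_diagonal(m_new, 0.0)

        if config.stop_criterion == "ls" and cand_ls is not None:
            err = cand_ls  # winner's LS is exactly the stop error
        else:
            err = stop_error(
                DistanceMatrix(labels, m_new), DistanceMatrix(labels, m_old),
                tree, config,
            )
        trace.append(err)
        if err < old_error:
            old_error = err
            prev_vals = m_new.copy()
            prev_tree = tree
        else:
            converged = True
            break

    final = prev_vals
    final[obs] = obs_ref[obs]
    final = np.where(mask & ~mask.T, final.T, final)  # mirror one-sided pairs
    np.fill_diagonal(final, 0.0)
    imputed = DistanceMatrix(labels, final)
    tree_final = prev_tree if prev_tree is not None else nj_tree(imputed)
    return ImputationResult(
        imputed=imputed, tree=tree_final, iterations=iterations,
        error_trace=trace, config=config, converged=converged,
    )
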