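"""Selection method S2: greedy exchange on the E(S^2) diversity criterion.

Given a standardized genotype matrix, the algorithm keeps a selected set X0
of fixed size and a candidate pool X1, and per iteration evaluates every
single-RIL exchange between the two sets, committing the one exchange that
most improves the criterion. The criterion is the trace of (X0'X0)^2 — the
sum of squared marker-by-marker similarities of the sample — computed via
the Gram-matrix identity trace((X'X)^2) = trace((XX')^2) so cost scales
with the sample size, not the marker count. Lower values correspond to
nearer-orthogonal, more genetically diverse samples, so ``max_diversity``
minimizes the criterion and ``min_diversity`` maximizes it.

An off-diagonal-only variant (excluding the squared diagonal of S = X0'X0)
is available; the two differ by the sum of squared column norms of X0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DIRECTIONS = ("max_diversity", "min_diversity")
VARIANTS = ("trace", "offdiag")


class SsdError(ValueError):
    """Invalid exchange-algorithm request."""


@dataclass
class SsdResult:
    """Outcome of one exchange run."""

    selected: np.ndarray           # sorted indices into the candidate matrix
    criterion: float
    iterations: int
    history: list[float]           # criterion after each improving iteration
    direction: str
    variant: str
    n_evaluations: int             # total criterion evaluations across iterations
    seed: int


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns on the FULL candidate set; drop constant columns.

    Returns ``(Xs, kept)``. Subsamples are never re-standardized: the whole
    point of the criterion is to compare subsamples on a common scale.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    return (X[:, kept] - mean[kept]) / sd[kept], kept


def es2(X0: np.ndarray, variant: str = "trace") -> float:
    """Diversity criterion of a selected submatrix.

    ``trace``: trace((X0'X0)^2) == squared Frobenius norm of X0 X0'.
    ``offdiag``: same minus the squared diagonal of S = X0'X0.
    """
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    if X0.shape[0] == 0:
        raise SsdError("empty selection")
    if variant not in VARIANTS:
        raise SsdError(f"unknown variant {variant!r}")
    K = X0 @ X0.T
    crit = float(np.sum(K * K))
    if variant == "offdiag":
        diag_s = np.sum(X0 * X0, axis=0)   # diagonal of X0'X0, length p
        crit -= float(np.sum(diag_s**2))
    return crit


@dataclass
class SsdState:
    """Selected/pool split plus cached Gram quantities for fast swaps."""

    X: np.ndarray                   # standardized full candidate matrix
    selected: np.ndarray            # positions into X, |selected| fixed
    pool: np.ndarray
    direction: str
    variant: str = "trace"
    criterion: float = field(init=False)
    history: list[float] = field(init=False, default_factory=list)
    _K: np.ndarray = field(init=False, repr=False)
    _diag_s: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise SsdError(f"unknown direction {self.direction!r}")
        if self.variant not in VARIANTS:
            raise SsdError(f"unknown variant {self.variant!r}")
        if len(self.selected) == 0:
            raise SsdError("empty selection")
        if set(self.selected) & set(self.pool):
            raise SsdError("selected and pool overlap")
        X0 = self.X[self.selected]
        self._K = X0 @ X0.T
        self._diag_s = np.sum(X0 * X0, axis=0)
        self.criterion = float(np.sum(self._K * self._K))
        if self.variant == "offdiag":
            self.criterion -= float(np.sum(self._diag_s**2))

    @property
    def minimizing(self) -> bool:
        return self.direction == "max_diversity"

    def improves(self, new: float) -> bool:
        return new < self.criterion if self.minimizing else new > self.criterion

    def apply_swap(self, m_pos: int, l_pos: int, new_criterion: float) -> None:
        """Exchange selected slot ``m_pos`` with pool slot ``l_pos``."""
        sel = self.selected.copy()
        old_row, new_row = sel[m_pos], self.pool[l_pos]
        sel[m_pos] = new_row
        pool = self.pool.copy()
        pool[l_pos] = old_row
        u = self.X[old_row]
        v = self.X[new_row]
        X0 = self.X[sel]
        cross = X0 @ v
        self._K[m_pos, :] = cross
        self._K[:, m_pos] = cross
        self._K[m_pos, m_pos] = v @ v
        self._diag_s += v * v - u * u
        self.selected, self.pool = sel, pool
        self.criterion = new_criterion


def _swap_criteria(state: SsdState) -> np.ndarray:
    """Criterion value after every (selected m, pool l) exchange.

    Returns an ``(n_selected, n_pool)`` matrix. Vectorized rank-one-row
    update of the Gram criterion:

        new = old - (2 * sum_j K[m,j]^2 - K[m,m]^2)
                  + (2 * sum_{j != m} (v_l . x_j)^2 + (v_l . v_l)^2)

    with x_j the retained selected rows and v_l the pool candidate.
    """
    X0 = state.X[state.selected]
    Xp = state.X[state.pool]
    K = state._K
    P = Xp @ X0.T                              # (pool, sel): v_l . x_j
    vnorm2 = np.einsum("ij,ij->i", Xp, Xp)     # v_l . v_l
    row_k2 = np.einsum("ij,ij->i", K, K)       # sum_j K[m,j]^2
    diag_k = np.diag(K)
    row_p2 = np.einsum("ij,ij->i", P, P)       # sum_j P[l,j]^2
    remove = 2.0 * row_k2 - diag_k**2          # (sel,)
    add = 2.0 * (row_p2[:, None] - P**2) + (vnorm2**2)[:, None]  # (pool, sel)
    trace_new = state.criterion - remove[None, :] + add
    if state.variant == "trace":
        return trace_new.T
    # off-diagonal variant: also track the change of sum(diag(S)^2)
    d = state._diag_s
    sd2 = float(np.sum(d**2))
    trace_new = trace_new + sd2  # state.criterion excluded diag; add it back
    A = X0 * X0                                # (sel, p)
    B = Xp * Xp                                # (pool, p)
    dU = A @ d
    dV = B @ d
    qU = np.einsum("ij,ij->i", A, A)
    qV = np.einsum("ij,ij->i", B, B)
    cross = B @ A.T                            # sum_j u^2 v^2
    new_sd2 = sd2 + 2.0 * (dV[:, None] - dU[None, :]) + (
        qV[:, None] - 2.0 * cross + qU[None, :]
    )
    return (trace_new - new_sd2).T


def best_swap(state: SsdState) -> tuple[int, int, float, int] | None:
    """Evaluate every exchange; return the single best improving one.

    Returns ``(m_pos, l_pos, new_criterion, n_evaluations)`` or ``None``
    when the pool is empty or no exchange improves the criterion. Ties are
    broken by the lowest (selected position, pool position) pair.
    """
    if len(state.pool) == 0:
        return None
    crit = _swap_criteria(state)               # (sel, pool)
    n_evals = crit.size
    flat = int(np.argmin(crit) if state.minimizing else np.argmax(crit))
    m_pos, l_pos = np.unravel_index(flat, crit.shape)
    new = float(crit[m_pos, l_pos])
    if not state.improves(new):
        return None
    return int(m_pos), int(l_pos), new, n_evals


def run_exchange(
    X: np.ndarray,
    n_sample: int,
    direction: str = "max_diversity",
    seed: int = 0,
    variant: str = "trace",
    pre_standardized: bool = False,
    max_iterations: int | None = None,
) -> SsdResult:
    """Run the full exchange algorithm from a seeded random split.

    Stops at the first iteration whose best exchange no longer improves the
    criterion; the returned history holds the starting criterion followed by
    the criterion after each improving iteration (strictly monotone).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= n_sample <= n:
        raise SsdError(f"n_sample must be in [1, {n}], got {n_sample}")
    Xs = X if pre_standardized else standardize(X)[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    state = SsdState(
        X=Xs,
        selected=np.sort(perm[:n_sample]),
        pool=np.sort(perm[n_sample:]),
        direction=direction,
        variant=variant,
    )
    history = [state.criterion]
    total_evals = 0
    iterations = 0
    while max_iterations is None or iterations < max_iterations:
        move = best_swap(state)
        if move is None:
            break
        m_pos, l_pos, new, n_evals = move
        total_evals += n_evals
        state.apply_swap(m_pos, l_pos, new)
        history.append(new)
        iterations += 1
    return SsdResult(
        selected=np.sort(state.selected),
        criterion=state.criterion,
        iterations=iterations,
        history=history,
        direction=direction,
        variant=variant,
        n_evaluations=total_evals,
        seed=int(seed),
    )
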