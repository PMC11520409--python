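"""Unbalanced entropic optimal transport between latent spot embeddings.

The alignment between two slices is a nonnegative plan ``T`` (n_x × n_y)
minimizing

    <C, T> - eps * H(T) + rho1 * KL(T 1 || a) + rho2 * KL(T^T 1 || b)

where ``C`` is the matrix of Euclidean distances between latent embeddings,
``H(T) = -sum T (log T - 1)`` is the (shifted) entropy, and the KL terms are
generalized Kullback-Leibler divergences ``KL(u||v) = sum u log(u/v) - u + v``
penalizing deviation of the plan's marginals from the reference spot weights
``a`` and ``b``.  Finite ``rho`` lets mass be created/destroyed, which is what
permits *partial* slice alignment; ``rho = inf`` recovers a hard marginal
constraint.

The solver is an inexact proximal-point scheme: each outer step re-centers the
Sinkhorn kernel on the current plan, ``G_ij = T_ij * exp(-C_ij / eps)``, and a
short inner loop of unbalanced Sinkhorn scalings

    alpha <- (a / (G beta))^(rho1 / (rho1 + eps))
    beta  <- (b / (G^T alpha))^(rho2 / (rho2 + eps))

updates the plan ``T = diag(alpha) G diag(beta)``.  With the default all-ones
initial plan the first outer step is exactly a plain entropic UOT solve of the
objective above; further re-centered steps anneal the entropic smoothing away,
so the outer loop monitors the objective and keeps only refreshes that
decrease it.  This makes the returned plan a minimizer of the stated
objective rather than of its zero-entropy limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "CostMatrix",
    "TransportPlan",
    "Matching",
    "latent_cost",
    "solve_uot",
    "uot_objective",
    "uot_loss",
    "max_probability_matching",
]

UNMATCHED = -1


@dataclass
class CostMatrix:
    """Pairwise latent-space cost between two slices' spots."""

    C: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2:
            raise ValueError("cost matrix must be 2-D")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("cost matrix has non-finite entries")
        if np.any(self.C < 0):
            raise ValueError("cost matrix has negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.C.shape


@dataclass
class TransportPlan:
    """Soft spot-to-spot correspondence with its solver metadata."""

    T: np.ndarray
    epsilon: float
    rho1: float
    rho2: float
    a: np.ndarray
    b: np.ndarray
    n_iter_used: int = 0
    converged: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.T.shape

    def mass(self) -> float:
        return float(self.T.sum())

    def row_marginal(self) -> np.ndarray:
        return self.T.sum(axis=1)

    def col_marginal(self) -> np.ndarray:
        return self.T.sum(axis=0)


@dataclass
class Matching:
    """Hard row-argmax matching derived from a transport plan.

    ``pi[i]`` is the target index matched to source spot ``i`` or
    ``UNMATCHED`` (-1) when the row carries less than ``min_mass``.
    """

    M: np.ndarray
    pi: np.ndarray

    @property
    def n_matched(self) -> int:
        return int(np.sum(self.pi != UNMATCHED))

    def matched_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        rows = np.nonzero(self.pi != UNMATCHED)[0]
        return rows, self.pi[rows]


def latent_cost(z_x: np.ndarray, z_y: np.ndarray, normalize: bool = False,
                squared: bool = False) -> CostMatrix:
    """Euclidean distance between latent embeddings, ``C_ij = ||z_xi - z_yj||_2``.

    ``normalize=True`` divides by ``max(C)`` so that the entropic scale
    ``eps`` has a problem-independent meaning.  ``squared=True`` uses the
    squared distance instead.
    """
    z_x = np.asarray(z_x, dtype=float)
    z_y = np.asarray(z_y, dtype=float)
    if z_x.ndim != 2 or z_y.ndim != 2 or z_x.shape[1] != z_y.shape[1]:
        raise ValueError(
            f"latent dimension mismatch: {z_x.shape} vs {z_y.shape}")
    # |x-y|^2 = |x|^2 + |y|^2 - 2 x.y, clipped for roundoff
    sq = (
        np.sum(z_x**2, axis=1)[:, None]
        + np.sum(z_y**2, axis=1)[None, :]
        - 2.0 * z_x @ z_y.T
    )
    np.maximum(sq, 0.0, out=sq)
    C = sq if squared else np.sqrt(sq)
    if normalize:
        m = C.max()
        if m > 0:
            C = C / m
    return CostMatrix(C, normalized=normalize)


def _exponent(rho: float, epsilon: float) -> float:
    """Sinkhorn scaling exponent rho/(rho+eps); exactly 1 for rho = inf."""
    if np.isinf(rho):
        return 1.0
    return rho / (rho + epsilon)


def uot_objective(C: np.ndarray, T: np.ndarray, epsilon: float, rho1: float,
                  rho2: float, a: np.ndarray, b: np.ndarray) -> float:
    """Evaluate the unbalanced entropic OT objective at a plan ``T``.

    Hard-constraint (`rho = inf`) marginals contribute 0 when satisfied and
    +inf otherwise (within a 1e-9 mass tolerance).
    """
    C = np.asarray(C, dtype=float)
    T = np.asarray(T, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        xlogx = np.where(T > 0, T * np.log(np.where(T > 0, T, 1.0)), 0.0)
    transport = float((C * T).sum())
    entropy = -float((xlogx - T).sum())  # H(T) = -sum T(log T - 1)
    total = transport - epsilon * entropy

    def _kl(u: np.ndarray, v: np.ndarray, rho: float) -> float:
        if np.isinf(rho):
            return 0.0 if np.max(np.abs(u - v)) < 1e-9 else np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(u > 0, u * np.log(np.where(u > 0, u, 1.0) / v), 0.0)
        return rho * float((term - u + v).sum())

    total += _kl(T.sum(axis=1), np.asarray(a, float), rho1)
    total += _kl(T.sum(axis=0), np.asarray(b, float), rho2)
    return total


def solve_uot(
    C: CostMatrix | np.ndarray,
    epsilon: float = 0.05,
    rho1: float = 1.0,
    rho2: float = 1.0,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    T_init: np.ndarray | None = None,
    n_outer: int = 50,
    n_inner: int = 10,
    tol: float = 1e-6,
) -> TransportPlan:
    """Solve unbalanced entropic OT by inexact proximal-point Sinkhorn.

    Parameters
    ----------
    C
        Nonnegative cost matrix (``CostMatrix`` or array), typically
        max-normalized latent distances.
    epsilon
        Entropic smoothing of each proximal subproblem. Below 1e-2 the
        scalings run in the log domain for numerical safety.
    rho1, rho2
        Marginal KL penalties for rows and columns; ``np.inf`` enforces the
        marginal exactly. Partial alignment uses ``rho1=inf, rho2=0.01`` so
        every source spot transports its full mass while target spots are
        free to be skipped.
    a, b
        Spot weights; default uniform ``1/n_x`` and ``1/n_y``.
    T_init
        Initial plan, default the all-ones matrix (so the first proximal step
        is an exact entropic UOT solve; see module docstring).
    n_outer, n_inner, tol
        Max proximal steps, scaling sweeps per step, and the max-abs
        plan-change stopping tolerance.  Outer steps that increase the
        objective are rejected and stop the loop.
    """
    Cm = C.C if isinstance(C, CostMatrix) else np.asarray(C, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if np.any(Cm < 0) or not np.all(np.isfinite(Cm)):
        raise ValueError("cost matrix must be finite and nonnegative")
    n_x, n_y = Cm.shape
    a = np.full(n_x, 1.0 / n_x) if a is None else np.asarray(a, dtype=float)
    b = np.full(n_y, 1.0 / n_y) if b is None else np.asarray(b, dtype=float)
    if a.shape != (n_x,) or b.shape != (n_y,):
        raise ValueError("marginal weight shapes do not match the cost matrix")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("marginal weights must be nonnegative")
    if T_init is None:
        T = np.ones((n_x, n_y))
    else:
        T = np.asarray(T_init, dtype=float)
        if T.shape != (n_x, n_y) or np.any(T < 0):
            raise ValueError("T_init must be a nonnegative n_x x n_y matrix")
        T = T.copy()

    f1 = _exponent(rho1, epsilon)
    f2 = _exponent(rho2, epsilon)
    log_domain = epsilon < 1e-2

    n_used = 0
    converged = False
    F_prev = np.inf
    for _ in range(max(n_outer, 1)):
        T_prev = T
        if log_domain:
            T = _prox_step_log(Cm, T, a, b, epsilon, f1, f2, n_inner)
        else:
            T = _prox_step(Cm, T, a, b, epsilon, f1, f2, n_inner)
        if not np.all(np.isfinite(T)):
            raise FloatingPointError(
                "transport scaling produced non-finite values; "
                "increase epsilon or use a normalized cost matrix")
        F = uot_objective(Cm, T, epsilon, rho1, rho2, a, b)
        if n_used > 0 and F > F_prev:
            # a re-centered kernel step that raises the objective means the
            # proximal annealing has passed the entropic optimum: keep the
            # previous plan
            T = T_prev
            converged = True
            break
        n_used += 1
        F_prev = F
        if np.max(np.abs(T - T_prev)) < tol:
            converged = True
            break

    return TransportPlan(T=T, epsilon=epsilon, rho1=rho1, rho2=rho2, a=a, b=b,
                         n_iter_used=n_used, converged=converged)


def _prox_step(Cm, T, a, b, epsilon, f1, f2, n_inner):
    """One proximal step in the standard domain (Gauss-Seidel scalings)."""
    G = T * np.exp(-Cm / epsilon)
    n_x, n_y = G.shape
    alpha = np.ones(n_x)
    beta = np.ones(n_y)
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(n_inner):
            Gb = G @ beta
            alpha = _safe_pow_ratio(a, Gb, f1)
            Ga = G.T @ alpha
            beta = _safe_pow_ratio(b, Ga, f2)
        # end on the row scaling so a hard row constraint (rho1 = inf)
        # holds exactly in the returned plan
        Gb = G @ beta
        alpha = _safe_pow_ratio(a, Gb, f1)
    return (alpha[:, None] * G) * beta[None, :]


def _safe_pow_ratio(num, den, f):
    """(num/den)^f with 0/0 -> 0 (empty rows stay empty)."""
    out = np.zeros_like(num, dtype=float)
    pos = den > 0
    out[pos] = (num[pos] / den[pos]) ** f
    return out


def _prox_step_log(Cm, T, a, b, epsilon, f1, f2, n_inner):
    """One proximal step with log-domain scalings (small epsilon)."""
    with np.errstate(divide="ignore"):
        logG = np.where(T > 0, np.log(np.where(T > 0, T, 1.0)), -np.inf)
        logG = logG - Cm / epsilon
        log_a = np.where(a > 0, np.log(np.where(a > 0, a, 1.0)), -np.inf)
        log_b = np.where(b > 0, np.log(np.where(b > 0, b, 1.0)), -np.inf)
    n_x, n_y = Cm.shape
    lalpha = np.zeros(n_x)
    lbeta = np.zeros(n_y)

    def _row_update(lbeta):
        lGb = logsumexp(logG + lbeta[None, :], axis=1)
        out = f1 * (log_a - lGb)
        return np.where(np.isneginf(log_a) | np.isneginf(lGb), -np.inf, out)

    for _ in range(n_inner):
        lalpha = _row_update(lbeta)
        lGa = logsumexp(logG + lalpha[:, None], axis=0)
        lbeta = f2 * (log_b - lGa)
        lbeta = np.where(np.isneginf(log_b) | np.isneginf(lGa), -np.inf, lbeta)
    lalpha = _row_update(lbeta)
    logT = lalpha[:, None] + logG + lbeta[None, :]
    return np.exp(logT)


def uot_loss(C: CostMatrix | np.ndarray, plan: TransportPlan) -> float:
    """Transport term ``sum_ij C_ij T_ij`` with the plan held fixed.

    This is the alignment loss fed back to the autoencoder: its gradient
    flows through ``C`` (hence the embeddings) only, never through ``T``.
    """
    Cm = C.C if isinstance(C, CostMatrix) else np.asarray(C, dtype=float)
    if Cm.shape != plan.T.shape:
        raise ValueError("cost and plan shapes differ")
    return float((Cm * plan.T).sum())


def max_probability_matching(plan: TransportPlan,
                             min_mass: float = 0.0) -> Matching:
    """Row-argmax hard matching; ties break to the smallest target index.

    Rows whose maximum mass falls below ``min_mass`` are left unmatched
    (sentinel -1); with ``min_mass=0`` an all-zero row is still unmatched.
    """
    T = plan.T
    pi = np.argmax(T, axis=1)  # np.argmax takes the first (smallest) index
    row_max = T[np.arange(T.shape[0]), pi]
    threshold = max(min_mass, 0.0)
    if threshold == 0.0:
        unmatched = row_max <= 0.0
    else:
        unmatched = row_max < threshold
    pi = np.where(unmatched, UNMATCHED, pi)
    M = np.zeros_like(T, dtype=np.int8)
    rows = np.nonzero(pi != UNMATCHED)[0]
    M[rows, pi[rows]] = 1
    return Matching(M=M, pi=pi)


def export_plan(plan: TransportPlan, path, fmt: str = "triplet",
                threshold: float = 0.0) -> None:
    """Write a plan as sparse triplet TSV (i, j, T_ij) or dense CSV."""
    import pandas as pd

    if fmt == "dense":
        pd.DataFrame(plan.T).to_csv(path, index=False, header=False)
        return
    if fmt != "triplet":
        raise ValueError(f"unknown plan format {fmt!r}")
    i, j = np.nonzero(plan.T > threshold)
    pd.DataFrame({"i": i, "j": j, "T_ij": plan.T[i, j]}).to_csv(
        path, sep="\t", index=False)


def export_matching(matching: Matching, path) -> None:
    """Write matched (source, target) index pairs as 2-column TSV."""
    import pandas as pd

    rows, cols = matching.matched_pairs()
    pd.DataFrame({"source": rows, "target": cols}).to_csv(
        path, sep="\t", index=False)
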