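"""Mahalanobis metric learning over pair-similarity vectors.

Expert similarity scores on a small labeled pair set are converted to
constraint classes (must-link / general-link / cannot-link by score tertiles).
The metric matrix C is learned by minimizing the trace quotient

    tr(A S_w Aᵀ) / tr(A S_b Aᵀ)

over row-orthonormal projections A (r x d), where S_w and S_b are the within-
and between-class scatter matrices of the labeled samples, via the decomposed
Newton iteration on the quotient value: at each step A is the eigenbasis of
the r smallest eigenvalues of (S_w − λ S_b) and λ is updated to the achieved
quotient.  C = AᵀA is positive semi-definite by construction and defines the
Mahalanobis distance d(x, y) = sqrt((x − y)ᵀ C (x − y)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PairSample",
    "MetricResult",
    "TraceQuotientMetricLearner",
    "assign_constraints",
    "scatter_matrices",
    "solve_trace_quotient",
    "mahalanobis_distance",
    "CONSTRAINT_CLASSES",
]

CONSTRAINT_CLASSES = ("cannot-link", "general-link", "must-link")


@dataclass
class PairSample:
    """An unordered patient pair with its similarity vector and, when labeled,
    an expert score in [0, 1] and a derived constraint class."""

    id_a: str
    id_b: str
    v: np.ndarray
    score: float | None = None
    constraint: str | None = None

    def __post_init__(self):
        if self.score is not None and not (0 <= self.score <= 1):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        if self.constraint is not None:
            if self.score is None:
                raise ValueError("constraint present without a score")
            if self.constraint not in CONSTRAINT_CLASSES:
                raise ValueError(f"unknown constraint {self.constraint!r}")


def assign_constraints(scores):
    """Assign must-/general-/cannot-link constraints by score tertiles.

    Rank-based thirds: the lowest third of scores becomes cannot-link, the
    middle third general-link, the top third must-link.  Ties are broken by
    input index (stable sort) and group sizes differ by at most one.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 scores to form tertiles, got {n}")
    if np.all(scores == scores[0]):
        warnings.warn("all similarity scores are equal; tertile assignment is "
                      "degenerate and falls back to input order")
    order = np.argsort(scores, kind="stable")
    out = np.empty(n, dtype=object)
    for label, chunk in zip(CONSTRAINT_CLASSES, np.array_split(order, 3)):
        out[chunk] = label
    return out


def scatter_matrices(V, constraints):
    """Within- and between-class scatter over all C(n, 2) labeled sample pairs.

    S_w sums (v_p − v_q)(v_p − v_q)ᵀ over same-constraint pairs, S_b over
    different-constraint pairs; S_w + S_b is the total pair scatter.  Computed
    by the exact closed form n Σ v vᵀ − (Σ v)(Σ v)ᵀ per group, which equals
    the brute-force enumeration.

    Returns ``(S_w, S_b, n_within, n_between)``.
    """
    V = np.asarray(V, dtype=float)
    constraints = np.asarray(constraints, dtype=object)
    if V.ndim != 2 or V.shape[0] != constraints.shape[0]:
        raise ValueError("V must be (n_samples, d) aligned with constraints")
    classes = sorted(set(constraints))
    if len(classes) < 2:
        raise ValueError("scatter matrices need at least 2 constraint classes "
                         "(S_b is undefined with a single class)")
    n, d = V.shape

    def pair_scatter(M):
        m = M.shape[0]
        s = M.sum(axis=0)
        return m * (M.T @ M) - np.outer(s, s)

    S_total = pair_scatter(V)
    S_w = np.zeros((d, d))
    n_within = 0
    for c in classes:
        Mc = V[constraints == c]
        S_w += pair_scatter(Mc)
        n_within += Mc.shape[0] * (Mc.shape[0] - 1) // 2
    S_b = S_total - S_w
    n_between = n * (n - 1) // 2 - n_within
    # symmetrize against floating-point drift
    S_w = (S_w + S_w.T) / 2
    S_b = (S_b + S_b.T) / 2
    return S_w, S_b, n_within, n_between


@dataclass
class MetricResult:
    """A learned Mahalanobis metric: projection A (r x d, orthonormal rows),
    C = AᵀA, the achieved trace quotient, and iteration diagnostics."""

    A: np.ndarray
    C: np.ndarray
    quotient: float
    n_iter: int
    converged: bool
    history: list = field(default_factory=list)


def _canonical_sign(A: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip each row so its first component of magnitude > tol is positive."""
    A = A.copy()
    for i in range(A.shape[0]):
        nz = np.flatnonzero(np.abs(A[i]) > tol)
        if nz.size and A[i, nz[0]] < 0:
            A[i] = -A[i]
    return A


def solve_trace_quotient(S_w, S_b, r: int, tol: float = 1e-8,
                         max_iter: int = 100) -> MetricResult:
    """Minimize tr(A S_w Aᵀ) / tr(A S_b Aᵀ) over row-orthonormal A (r x d).

    Decomposed Newton iteration on the quotient λ, initialized at λ = 0 so the
    first iterate is the minimum-within-scatter subspace: A_t collects the
    eigenvectors of the r smallest eigenvalues of (S_w − λ_t S_b), then
    λ_{t+1} = tr(A_t S_w A_tᵀ) / tr(A_t S_b A_tᵀ).  From the first achieved
    quotient onward the λ sequence is non-increasing and converges to the
    optimum; iteration stops when successive values differ by less than
    ``tol`` or after ``max_iter`` steps (warning + best iterate).
    """
    S_w = np.asarray(S_w, dtype=float)
    S_b = np.asarray(S_b, dtype=float)
    d = S_w.shape[0]
    if S_w.shape != (d, d) or S_b.shape != (d, d):
        raise ValueError("S_w and S_b must be square matrices of equal size")
    if not (1 <= r < d):
        raise ValueError(f"projection rank r must satisfy 1 <= r < d = {d}, got {r} "
                         "(r = d forces C = I)")
    if np.linalg.norm(S_b) < 1e-12:
        raise ValueError("S_b is (numerically) zero; the trace quotient is undefined")

    # directions with no scatter at all (components constant over the labeled
    # samples) leave the quotient 0/0-undefined; solve within the span of the
    # total scatter and embed the projection back, as in discriminant analysis
    wT, UT = eigh(S_w + S_b)
    keep = wT > 1e-10 * max(float(wT.max()), 1.0)
    P = UT[:, keep]
    d_eff = P.shape[1]
    if d_eff > r and d_eff < d:
        res = solve_trace_quotient(P.T @ S_w @ P, P.T @ S_b @ P, r, tol, max_iter)
        A = _canonical_sign(res.A @ P.T)
        C = A.T @ A
        return MetricResult(A=A, C=(C + C.T) / 2, quotient=res.quotient,
                            n_iter=res.n_iter, converged=res.converged,
                            history=res.history)

    lam = 0.0
    history = []
    A = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        M = S_w - lam * S_b
        _, U = eigh(M)
        A = _canonical_sign(U[:, :r].T)
        W = float(np.trace(A @ S_w @ A.T))
        B = float(np.trace(A @ S_b @ A.T))
        if B < 1e-15:
            warnings.warn("between-class scatter vanishes in the selected "
                          "subspace; stopping at the current iterate")
            break
        lam_new = W / B
        history.append(lam_new)
        if abs(lam_new - lam) < tol:
            lam = lam_new
            converged = True
            break
        lam = lam_new
    if not converged:
        warnings.warn(f"trace-quotient Newton iteration did not converge within "
                      f"{max_iter} iterations; returning the best iterate")
    C = A.T @ A
    C = (C + C.T) / 2
    return MetricResult(A=A, C=C, quotient=lam, n_iter=n_iter,
                        converged=converged, history=history)


def mahalanobis_distance(v_p, v_q, C) -> float:
    """sqrt((v_p − v_q)ᵀ C (v_p − v_q)) for a PSD matrix C."""
    v_p = np.asarray(v_p, dtype=float)
    v_q = np.asarray(v_q, dtype=float)
    C = np.asarray(C, dtype=float)
    if v_p.shape != v_q.shape or C.shape != (v_p.shape[0], v_p.shape[0]):
        raise ValueError("dimension mismatch between vectors and metric matrix")
    delta = v_p - v_q
    q = float(delta @ C @ delta)
    return float(np.sqrt(max(q, 0.0)))


class TraceQuotientMetricLearner(BaseEstimator, TransformerMixin):
    """Learn a Mahalanobis metric over pair-similarity vectors from expert
    scores.

    ``fit(X, y)`` takes the labeled pair vectors ``X`` (n_pairs, d) and their
    expert similarity scores ``y`` in [0, 1]; scores are converted to tertile
    constraints, scatter matrices accumulated over all labeled sample pairs,
    and the trace quotient minimized by Newton iteration.

    Parameters
    ----------
    rank : projection rank r (default 2, the discriminant-analysis convention
        of one less than the number of constraint classes); must be < d.
    tol, max_iter : Newton stopping rule.

    Attributes
    ----------
    components_ : (rank, d) row-orthonormal projection A.
    metric_matrix_ : (d, d) PSD matrix C = AᵀA.
    quotient_ : achieved trace-quotient value λ*.
    constraints_ : per-sample constraint classes used for the scatter sums.
    n_iter_, converged_, history_ : iteration diagnostics.
    """

    def __init__(self, rank: int = 2, tol: float = 1e-8, max_iter: int = 100):
        self.rank = rank
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_pairs, d) aligned with scores y")
        self.constraints_ = assign_constraints(y)
        S_w, S_b, nw, nb = scatter_matrices(X, self.constraints_)
        self.scatter_within_, self.scatter_between_ = S_w, S_b
        self.n_within_pairs_, self.n_between_pairs_ = nw, nb
        res = solve_trace_quotient(S_w, S_b, self.rank, self.tol, self.max_iter)
        self.components_ = res.A
        self.metric_matrix_ = res.C
        self.quotient_ = res.quotient
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.history_ = res.history
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Project pair vectors into the learned r-dimensional metric space
        (Euclidean distance there equals the learned Mahalanobis distance)."""
        X = np.asarray(X, dtype=float)
        return X @ self.components_.T

    def pair_distance(self, v_p, v_q) -> float:
        return mahalanobis_distance(v_p, v_q, self.metric_matrix_)
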