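"""Random-walk-with-restart diffusion and low-dimensional node embeddings.

Each network is summarised by its matrix of diffusion states: row *i* is the
stationary visitation distribution of a walker that starts at gene *i* and
restarts there with probability ``alpha`` each step. Genes occupying similar
network positions have similar diffusion states and, by the guilt-by-
association premise, similar functions.

The n-dimensional diffusion states are noisy and high-dimensional, so they
are compacted: ``R = ln(S + 1/n)`` (the pseudo-count keeps the log finite)
followed by a truncated SVD, keeping ``X = U_d sqrt(Sigma_d)`` as node
features and ``W = V_d sqrt(Sigma_d)`` as context features. This is the
closed-form surrogate for fitting the softmax model
``s_hat[i, j] = exp(x_i . w_j) / sum_j' exp(x_i . w_j')`` by KL divergence;
:func:`kl_objective` evaluates that divergence as a diagnostic but is never
on the production path. Per-network embeddings are concatenated column-wise
so each network contributes its own d-dimensional block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import logsumexp

from .network_io import TransitionMatrix, WeightedGraph, to_transition

__all__ = [
    "DiffusionStates",
    "Embedding",
    "FeatureMatrix",
    "rwr_diffusion",
    "rwr_closed_form",
    "log_transform",
    "svd_embed",
    "kl_objective",
    "embed_network",
    "concat_embeddings",
]


@dataclass
class DiffusionStates:
    """Stationary RWR distributions, one per source gene (rows of ``S``).

    Every row sums to 1 (dangling sources sit exactly on their restart
    distribution); ``alpha`` in (0, 1] is the restart probability. Larger
    ``alpha`` keeps mass near the source, weighting local over global
    topology.
    """

    S: np.ndarray
    alpha: float
    iterations: int = 0
    converged: bool = True

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass
class Embedding:
    """Truncated-SVD factors of the log-diffusion matrix for one network."""

    X: np.ndarray  # n x d node features, U_d sqrt(Sigma_d)
    W: np.ndarray  # n x d context features, V_d sqrt(Sigma_d)
    d: int
    singular_values: np.ndarray
    name: str = ""

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class FeatureMatrix:
    """Column-wise concatenation of K per-network embeddings (n x K*d)."""

    X_full: np.ndarray
    network_order: list[str] = field(default_factory=list)
    block_widths: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X_full.shape[0]

    def block(self, k: int) -> np.ndarray:
        """The k-th network's feature block, bit-identical to its input X."""
        start = int(np.sum(self.block_widths[:k]))
        return self.X_full[:, start : start + self.block_widths[k]]


def _walk_matrix(M: TransitionMatrix) -> sp.csr_matrix:
    # Row-stochastic orientation for right-multiplication by row vectors:
    # for a symmetrized network the transpose of the column-stochastic M is
    # D^-1 A, so s <- s M^T is a mass-conserving walk (dangling rows aside).
    return M.M.T.tocsr()


def rwr_diffusion(
    M: TransitionMatrix,
    alpha: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> DiffusionStates:
    """Iterate all n diffusion states to convergence simultaneously.

    ``S <- (1 - alpha) S P + alpha I`` with ``P`` the walk matrix, starting
    from ``S = I``; iteration stops when the largest per-row L1 change drops
    below ``tol``. Mass stepping onto a dangling (isolated) node cannot move
    on, so it is redirected wholly to the restart distribution, keeping every
    row an exact probability distribution.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    n = M.n
    if alpha == 1.0:
        return DiffusionStates(S=np.eye(n), alpha=alpha, iterations=0)
    P = _walk_matrix(M)
    S = np.eye(n)
    restart = np.eye(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        S_new = (1.0 - alpha) * (S @ P) + alpha * restart
        deficit = 1.0 - S_new.sum(axis=1)  # (1-alpha) * mass on dangling nodes
        if np.any(deficit > 1e-15):
            S_new[np.arange(n), np.arange(n)] += deficit
        delta = np.abs(S_new - S).sum(axis=1).max()
        S = S_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"RWR did not converge within {max_iter} iterations "
            f"(last L1 change {delta:.3g})",
            RuntimeWarning,
        )
    return DiffusionStates(S=S, alpha=alpha, iterations=it, converged=converged)


def rwr_closed_form(
    M: TransitionMatrix, alpha: float, max_n: int = 500
) -> DiffusionStates:
    """Exact stationary diffusion states by dense linear solve.

    Solves the fixed point ``s_i = (1-alpha) s_i P_i + alpha e_i`` directly;
    ``P_i`` includes the redirect of dangling mass to source *i*. Intended as
    an independent oracle on small instances, hence the size cap.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    n = M.n
    if n > max_n:
        raise ValueError(f"closed-form solve capped at n={max_n}, got n={n}")
    if alpha == 1.0:
        return DiffusionStates(S=np.eye(n), alpha=alpha)
    P = _walk_matrix(M).toarray()
    if not M.dangling:
        # s_i = alpha e_i (I - (1-alpha) P)^-1, all rows at once
        S = alpha * np.linalg.inv(np.eye(n) - (1.0 - alpha) * P)
    else:
        z = np.zeros(n)
        z[list(M.dangling)] = 1.0  # rows of P with no outgoing mass
        S = np.empty((n, n))
        for i in range(n):
            Pi = P + np.outer(z, _unit(n, i))
            rhs = alpha * _unit(n, i)
            # transpose so np.linalg.solve sees a standard A x = b
            S[i] = np.linalg.solve((np.eye(n) - (1.0 - alpha) * Pi).T, rhs)
    return DiffusionStates(S=S, alpha=alpha)


def _unit(n: int, i: int) -> np.ndarray:
    e = np.zeros(n)
    e[i] = 1.0
    return e


def log_transform(states: DiffusionStates) -> np.ndarray:
    """``R[i, j] = ln(S[i, j] + 1/n)``; finite everywhere by the pseudo-count."""
    n = states.n
    return np.log(states.S + 1.0 / n)


def svd_embed(R: np.ndarray, d: int) -> Embedding:
    """Best rank-d factorisation of R into node and context features.

    ``X = U_d sqrt(Sigma_d)``, ``W = V_d sqrt(Sigma_d)`` so ``X W^T`` is the
    Eckart-Young optimal rank-d approximation of R. Sign ambiguity of each
    singular-vector pair is fixed by making the largest-magnitude entry of
    the left vector positive, so embeddings are reproducible across runs and
    BLAS builds.
    """
    R = np.asarray(R, dtype=float)
    n = min(R.shape)
    if not 1 <= d <= n:
        raise ValueError(f"d must be in [1, {n}], got {d}")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for k in range(n):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] *= -1.0
            V[:, k] *= -1.0
    root = np.sqrt(s[:d])
    return Embedding(
        X=U[:, :d] * root,
        W=V[:, :d] * root,
        d=d,
        singular_values=s[:d].copy(),
    )


def kl_objective(states: DiffusionStates, X: np.ndarray, W: np.ndarray) -> float:
    """Mean KL divergence between true diffusion states and the softmax model.

    ``(1/n) sum_i KL(s_i || softmax_j(x_i . w_j))``. Diagnostic only: the
    production embedding minimises a log/SVD surrogate of this objective, and
    this function quantifies how well a given (X, W) pair explains the walks.
    """
    S = states.S
    if X.shape[0] != S.shape[0] or W.shape[0] != S.shape[1]:
        raise ValueError("factor shapes do not match the diffusion states")
    logits = X @ W.T
    log_shat = logits - logsumexp(logits, axis=1, keepdims=True)
    log_s = np.log(np.where(S > 0, S, 1.0))  # 0 log 0 := 0
    terms = np.where(S > 0, S * (log_s - log_shat), 0.0)
    return float(terms.sum(axis=1).mean())


def embed_network(
    g: WeightedGraph,
    alpha: float = 0.5,
    d: int = 100,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> Embedding:
    """Full per-network pipeline: transition -> RWR -> log -> truncated SVD.

    Defaults follow the reference yeast setting (alpha 0.5, d 100); human
    networks use d=300. Deterministic given its inputs.
    """
    M = to_transition(g)
    states = rwr_diffusion(M, alpha=alpha, tol=tol, max_iter=max_iter)
    emb = svd_embed(log_transform(states), d)
    emb.name = g.name
    return emb


def concat_embeddings(embeddings: list[Embedding]) -> FeatureMatrix:
    """Stack K per-network embeddings into one n x (sum of d) feature matrix."""
    if not embeddings:
        raise ValueError("need at least one embedding")
    n = embeddings[0].n
    for e in embeddings:
        if e.n != n:
            raise ValueError(
                f"embedding {e.name!r} has {e.n} genes, expected {n}"
            )
    return FeatureMatrix(
        X_full=np.hstack([e.X for e in embeddings]),
        network_order=[e.name for e in embeddings],
        block_widths=[e.X.shape[1] for e in embeddings],
    )
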