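"""Dual-regularized NMF: objective, multiplicative updates, fit loop.

The model factorizes a nonnegative expression matrix ``X`` (``g`` samples
by ``s`` biomarkers) as ``X ~ W H`` with ``W`` (``g x k``) and ``H``
(``k x s``) nonnegative, minimizing

    J(W, H) = ||X - W H||_F + alpha * ||W||_{2,1} + beta * T(H)

where ``||W||_{2,1}`` is the row-sparsity-inducing L2,1 norm of the basis
and ``T(H)`` is the topological-overlap penalty on the coefficient
columns (see :mod:`topconnmf.topology`).  Both matrices are updated by
multiplicative ratio rules which preserve nonnegativity; denominators
are floored at a small positive constant for numerical stability.

The basis penalty enters the ``W`` denominator through the iteratively
reweighted form ``(alpha/2) * D W`` with ``D = diag(1 / (2 ||w_i|| + eps))``
(default), which targets the stated L2,1 term; a ``literal`` mode
uses ``(alpha/2) * W`` instead, the ridge-like half-gradient form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import topology
from .errors import DimensionError, InvalidRankError
from .expression import as_values

logger = logging.getLogger(__name__)

PENALTY_REWEIGHTED = "reweighted"
PENALTY_LITERAL = "literal"


@dataclass
class FactorConfig:
    """Configuration of one factorization run.

    Parameters
    ----------
    k
        Factorization rank, ``1 <= k <= min(g, s)``.
    alpha
        Weight of the L2,1 basis penalty (default 0.0150, the grid-search
        optimum reported for the reference time-course datasets).
    beta
        Weight of the topology penalty on ``H`` (default 0.0095, same
        provenance).
    max_iter, tol
        Stop after ``max_iter`` alternating updates or when the relative
        total-cost change drops below ``tol``.
    max_backtracks
        Levels of geometric step damping the fit loop may try when a
        proposed multiplicative step would increase the total cost
        (see :func:`fit`); 0 disables damping (reject outright).
    floor_eps
        Flooring constant for denominators and non-finite entries.
    basis_penalty_mode
        ``"reweighted"`` (descends the stated L2,1 term) or
        ``"literal"``.
    tom_product_mode
        ``"matrix"`` or ``"hadamard"`` product inside the overlap matrix.
    gradient_mode
        ``"chain_rule"`` (default), ``"literal"`` or
        ``"finite_difference"`` for the topology gradient.
    """

    k: int
    alpha: float = 0.0150
    beta: float = 0.0095
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0
    floor_eps: float = 1e-10
    basis_penalty_mode: str = PENALTY_REWEIGHTED
    tom_product_mode: str = topology.MODE_MATRIX
    gradient_mode: str = topology.GRAD_CHAIN
    max_backtracks: int = 6

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidRankError(f"rank k={self.k} must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.floor_eps <= 0:
            raise ValueError("floor_eps must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.basis_penalty_mode not in (PENALTY_REWEIGHTED, PENALTY_LITERAL):
            raise ValueError(f"unknown basis penalty mode {self.basis_penalty_mode!r}")


@dataclass
class FactorPair:
    """Basis ``W`` (g x k) and coefficients ``H`` (k x s)."""

    W: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.W.ndim != 2 or self.H.ndim != 2:
            raise DimensionError("W and H must be 2-D")
        if self.W.shape[1] != self.H.shape[0]:
            raise DimensionError(
                f"inner dimensions differ: W is {self.W.shape}, H is {self.H.shape}"
            )

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class FactorResult:
    """Outcome of :func:`fit`: final factors plus per-iteration traces.

    ``n_rejected_steps`` counts proposed multiplicative steps the
    monotone safeguard refused because they would have increased the
    total cost (see :func:`fit`).
    """

    factors: FactorPair
    cost_trace: list[float]
    re_trace: list[float]
    n_iter: int
    converged: bool
    config: FactorConfig = field(repr=False)
    n_rejected_steps: int = 0


def floor_nonfinite(M: np.ndarray, eps: float, nonnegative: bool = True) -> np.ndarray:
    """Replace NaN/Inf entries by ``eps``; floor small entries for
    contract-nonnegative matrices.

    Every non-finite entry becomes ``eps``.  When ``nonnegative`` is true
    (the contract for W, H and update denominators), entries below ``eps``
    are also raised to ``eps`` so subsequent divisions stay well-behaved.
    """
    M = np.asarray(M, dtype=float)
    out = np.where(np.isfinite(M), M, eps)
    if nonnegative:
        out = np.maximum(out, eps)
    return out


def initialize_factors(X, k: int, seed: int = 0) -> FactorPair:
    """Random strictly-positive initial factors, deterministic given seed.

    Entries are uniform on ``(0, 1]`` scaled by ``sqrt(mean(X) / k)`` so
    that the initial product ``W H`` has magnitude comparable to ``X``.
    """
    Xv = as_values(X)
    g, s = Xv.shape
    if not 1 <= k <= min(g, s):
        raise InvalidRankError(f"rank k={k} outside [1, {min(g, s)}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(Xv.mean(), np.finfo(float).tiny) / k)
    W = (1.0 - rng.random((g, k))) * scale  # uniform on (0, 1]
    H = (1.0 - rng.random((k, s))) * scale
    return FactorPair(W=W, H=H)


def reconstruction_error(X, F: FactorPair) -> float:
    """Frobenius norm ``||X - W H||_F``."""
    Xv = as_values(X)
    if Xv.shape != (F.W.shape[0], F.H.shape[1]):
        raise DimensionError(
            f"X has shape {Xv.shape}, factors reconstruct "
            f"{(F.W.shape[0], F.H.shape[1])}"
        )
    return float(np.linalg.norm(Xv - F.W @ F.H, "fro"))


def l21_norm(W: np.ndarray) -> float:
    """L2,1 norm: sum over rows of the row-wise Euclidean norm."""
    W = np.asarray(W, dtype=float)
    return float(np.sum(np.sqrt(np.sum(W * W, axis=1))))


def total_cost(X, F: FactorPair, cfg: FactorConfig) -> float:
    """``||X - WH||_F + alpha ||W||_{2,1} + beta T(H)``."""
    cost = reconstruction_error(X, F)
    if cfg.alpha > 0:
        cost += cfg.alpha * l21_norm(F.W)
    if cfg.beta > 0:
        T, _ = topology.topology_penalty(
            F.H, cfg.k, cfg.floor_eps, cfg.tom_product_mode
        )
        cost += cfg.beta * T
    return float(cost)


def _basis_penalty(W: np.ndarray, cfg: FactorConfig) -> np.ndarray:
    """Denominator contribution of the basis regularizer."""
    if cfg.alpha == 0:
        return np.zeros_like(W)
    if cfg.basis_penalty_mode == PENALTY_LITERAL:
        return (cfg.alpha / 2.0) * W
    row_norms = np.sqrt(np.sum(W * W, axis=1))
    D = 1.0 / (2.0 * row_norms + cfg.floor_eps)
    return (cfg.alpha / 2.0) * (D[:, None] * W)


def update_basis(X, F: FactorPair, cfg: FactorConfig) -> np.ndarray:
    """One multiplicative update of the basis matrix.

    ``W' = W * (X H^T) / (W H H^T + P(W))`` elementwise, with the
    denominator floored at ``cfg.floor_eps``.
    """
    Xv = as_values(X)
    W, H = F.W, F.H
    if not (np.all(np.isfinite(W)) and np.all(np.isfinite(H))):
        logger.warning("non-finite factor entries floored before basis update")
        W = floor_nonfinite(W, cfg.floor_eps)
        H = floor_nonfinite(H, cfg.floor_eps)
    num = Xv @ H.T
    den = W @ (H @ H.T) + _basis_penalty(W, cfg)
    den = floor_nonfinite(den, cfg.floor_eps)
    Wn = W * (num / den)
    return floor_nonfinite(Wn, cfg.floor_eps, nonnegative=False)


def update_coefficients(X, F: FactorPair, cfg: FactorConfig) -> np.ndarray:
    """One multiplicative update of the coefficient matrix.

    The topology gradient ``T'`` is split into its positive and negative
    parts, the standard construction for multiplicative rules with
    signed regularizer gradients:

    ``H' = H * (W^T X + (beta/2) max(-T', 0))
           / (W^T W H + (beta/2) max(T', 0))``

    Both numerator and denominator stay nonnegative, so nonnegativity of
    ``H`` is preserved; discarding the negative part instead (denominator
    clipping alone) leaves the update unable to descend the topology
    term where it favors larger coefficients, and breaks the monotone
    decrease of the total cost in practice.
    """
    Xv = as_values(X)
    W, H = F.W, F.H
    if not (np.all(np.isfinite(W)) and np.all(np.isfinite(H))):
        logger.warning("non-finite factor entries floored before coefficient update")
        W = floor_nonfinite(W, cfg.floor_eps)
        H = floor_nonfinite(H, cfg.floor_eps)
    num = W.T @ Xv
    den = (W.T @ W) @ H
    if cfg.beta > 0:
        Tp = topology.topology_gradient(
            H,
            cfg.k,
            floor_eps=cfg.floor_eps,
            tom_mode=cfg.tom_product_mode,
            gradient_mode=cfg.gradient_mode,
        )
        num = num + (cfg.beta / 2.0) * np.maximum(-Tp, 0.0)
        den = den + (cfg.beta / 2.0) * np.maximum(Tp, 0.0)
    den = floor_nonfinite(den, cfg.floor_eps)
    Hn = H * (num / den)
    return floor_nonfinite(Hn, cfg.floor_eps, nonnegative=False)


def fit(X, cfg: FactorConfig) -> FactorResult:
    """Alternating multiplicative optimization of the regularized cost.

    Each iteration proposes a multiplicative basis step and then a
    coefficient step, flooring both.  Because the topology penalty is an
    elementwise quotient with poles where the centred Gram of ``H``'s
    columns vanishes, a raw multiplicative step can jump the cost (pole
    crossing / overshoot when the penalty gradient dominates the
    denominator).  The loop therefore applies a monotone safeguard with
    geometric backtracking: a proposed step ``M -> M * r`` is accepted
    only if it does not increase the total cost; otherwise damped steps
    ``M * r**theta`` with ``theta = 1/2, 1/4, ...`` are tried (up to
    ``cfg.max_backtracks`` levels, preserving positivity) and, failing
    all of them, the previous iterate is retained and the rejection
    counted.  With ``alpha = beta = 0`` the classical multiplicative
    update is monotone, so the first trial is always accepted and the
    iteration equals plain NMF exactly.

    Stops when the relative cost change falls below ``cfg.tol`` or after
    ``cfg.max_iter`` iterations.  Deterministic given ``cfg.seed``.
    """
    Xv = as_values(X)
    g, s = Xv.shape
    if not 1 <= cfg.k <= min(g, s):
        raise InvalidRankError(f"rank k={cfg.k} outside [1, {min(g, s)}]")
    F = initialize_factors(Xv, cfg.k, cfg.seed)
    cost_trace: list[float] = []
    re_trace: list[float] = []
    converged = False
    n_rejected = 0
    J_cur = total_cost(Xv, F, cfg)
    prev = None

    def try_step(which: str) -> tuple[FactorPair, float, bool]:
        nonlocal n_rejected
        if which == "W":
            cand = floor_nonfinite(update_basis(Xv, F, cfg), cfg.floor_eps)
            base = F.W
        else:
            cand = floor_nonfinite(update_coefficients(Xv, F, cfg), cfg.floor_eps)
            base = F.H
        ratio = cand / np.maximum(base, cfg.floor_eps)
        theta = 1.0
        for level in range(cfg.max_backtracks + 1):
            trial = cand if level == 0 else base * ratio**theta
            Ft = FactorPair(W=trial, H=F.H) if which == "W" else FactorPair(W=F.W, H=trial)
            Jt = total_cost(Xv, Ft, cfg)
            if Jt <= J_cur:
                return Ft, Jt, True
            theta /= 2.0
        n_rejected += 1
        logger.debug("%s step rejected after %d backtracks", which, cfg.max_backtracks)
        return F, J_cur, False

    for _ in range(cfg.max_iter):
        F, J_cur, _accepted = try_step("W")
        F, J_cur, _accepted = try_step("H")
        cost_trace.append(J_cur)
        re_trace.append(reconstruction_error(Xv, F))
        if prev is not None:
            rel = abs(J_cur - prev) / max(prev, cfg.floor_eps)
            if rel < cfg.tol:
                converged = True
                break
        prev = J_cur
    return FactorResult(
        factors=F,
        cost_trace=cost_trace,
        re_trace=re_trace,
        n_iter=len(cost_trace),
        converged=converged,
        config=replace(cfg),
        n_rejected_steps=n_rejected,
    )
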