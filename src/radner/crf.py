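"""Linear-chain conditional random field: scoring, likelihood, decoding.

A tag path y₁..y_T over K tags is scored against per-position emissions
e ∈ ℝ^{T×K} and chain parameters (transition matrix A ∈ ℝ^{K×K}, start and
end vectors) as

    s(y) = start[y₁] + Σₜ e[t, yₜ] + Σₜ A[yₜ₋₁, yₜ] + end[y_T].

Training maximizes the path log-likelihood  s(y*) − log Σ_y exp s(y); the
log-partition is computed by the forward recursion in log space, gradients
by forward–backward marginals, and decoding by Viterbi with deterministic
lowest-index tie-breaking.

All functions take integer tag indices; the label-string alphabet lives in
:mod:`radner.corpus_io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp


@dataclass
class CRFParameters:
    """Transition/start/end scores of a linear-chain CRF over K tags."""

    transitions: np.ndarray  # (K, K); [i, j] scores tag i -> tag j
    start: np.ndarray        # (K,)
    end: np.ndarray          # (K,)

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        K = self.K
        if self.transitions.shape != (K, K) or self.end.shape != (K,):
            raise ValueError("inconsistent CRF parameter shapes")
        for arr in (self.transitions, self.start, self.end):
            if not np.all(np.isfinite(arr) | (arr == -np.inf)):
                raise ValueError("CRF parameters must be finite (or -inf mask)")

    @property
    def K(self) -> int:
        return self.start.shape[0]

    @classmethod
    def zeros(cls, K: int) -> "CRFParameters":
        return cls(np.zeros((K, K)), np.zeros(K), np.zeros(K))


def _check(e: np.ndarray, p: CRFParameters) -> np.ndarray:
    e = np.asarray(e, dtype=float)
    if e.ndim != 2 or e.shape[0] < 1:
        raise ValueError("emissions must be a (T>=1, K) matrix")
    if e.shape[1] != p.K:
        raise ValueError(f"emissions have {e.shape[1]} tags, parameters {p.K}")
    return e


def path_score(e: np.ndarray, p: CRFParameters, tags: Sequence[int]) -> float:
    """Score of one tag path: start + emissions + transitions + end."""
    e = _check(e, p)
    y = np.asarray(tags, dtype=np.intp)
    if y.shape[0] != e.shape[0]:
        raise ValueError(f"{y.shape[0]} tags for {e.shape[0]} positions")
    s = p.start[y[0]] + e[np.arange(len(y)), y].sum() + p.end[y[-1]]
    if len(y) > 1:
        s += p.transitions[y[:-1], y[1:]].sum()
    return float(s)


def log_partition(e: np.ndarray, p: CRFParameters) -> float:
    """log Σ over all K^T paths of exp(path_score), via the forward recursion."""
    e = _check(e, p)
    alpha = p.start + e[0]
    for t in range(1, e.shape[0]):
        alpha = logsumexp(alpha[:, None] + p.transitions, axis=0) + e[t]
    return float(logsumexp(alpha + p.end))


def nll(e: np.ndarray, p: CRFParameters, gold: Sequence[int]) -> float:
    """Negative log-likelihood of the gold path; always >= 0."""
    return log_partition(e, p) - path_score(e, p, gold)


def viterbi(e: np.ndarray, p: CRFParameters) -> list[int]:
    """A maximum-score tag path; ties resolve to the lowest tag index."""
    e = _check(e, p)
    T, K = e.shape
    delta = p.start + e[0]
    back = np.zeros((T, K), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + p.transitions  # (from, to)
        back[t] = np.argmax(scores, axis=0)      # argmax -> first (lowest) index
        delta = scores[back[t], np.arange(K)] + e[t]
    y = int(np.argmax(delta + p.end))
    path = [y]
    for t in range(T - 1, 0, -1):
        y = int(back[t, y])
        path.append(y)
    return path[::-1]


def forward_backward(
    e: np.ndarray, p: CRFParameters
) -> tuple[np.ndarray, np.ndarray, float]:
    """Log forward/backward messages and the log-partition.

    alpha[t, k] sums paths ending in tag k at t (start and emissions up to t
    included); beta[t, k] sums continuations from tag k at t (emissions
    after t and the end score included).
    """
    e = _check(e, p)
    T, K = e.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    alpha[0] = p.start + e[0]
    for t in range(1, T):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + p.transitions, axis=0) + e[t]
    beta[T - 1] = p.end
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(p.transitions + e[t + 1] + beta[t + 1], axis=1)
    logZ = float(logsumexp(alpha[T - 1] + beta[T - 1]))
    return alpha, beta, logZ


def nll_and_grads(
    e: np.ndarray, p: CRFParameters, gold: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NLL of the gold path plus its exact gradients.

    Returns (nll, d_emissions, d_transitions, d_start, d_end).  Gradients
    are expectation-minus-observation: posterior marginals under the model
    minus the gold path's indicator counts.
    """
    e = _check(e, p)
    y = np.asarray(gold, dtype=np.intp)
    T, K = e.shape
    if y.shape[0] != T:
        raise ValueError(f"{y.shape[0]} tags for {T} positions")
    alpha, beta, logZ = forward_backward(e, p)

    unary = np.exp(alpha + beta - logZ)  # (T, K) posterior marginals
    d_e = unary.copy()
    d_e[np.arange(T), y] -= 1.0
    d_start = unary[0].copy()
    d_start[y[0]] -= 1.0
    d_end = unary[T - 1].copy()
    d_end[y[-1]] -= 1.0

    d_trans = np.zeros((K, K))
    for t in range(1, T):
        pair = alpha[t - 1][:, None] + p.transitions + e[t] + beta[t] - logZ
        d_trans += np.exp(pair)
    for t in range(1, T):
        d_trans[y[t - 1], y[t]] -= 1.0

    value = logZ - path_score(e, p, gold)
    return value, d_e, d_trans, d_start, d_end
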