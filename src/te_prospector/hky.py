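"""HKY85 substitution model: rate matrix, site evolution and pairwise ML distance.

The HKY85 model allows unequal base frequencies pi and a transition /
transversion rate ratio kappa.  The rate matrix is normalized so that branch
length equals the expected number of substitutions per site, and transition
probabilities are computed with a matrix exponential.  The pairwise distance
estimator maximizes the two-sequence likelihood numerically over (d, kappa)
with empirical pooled base frequencies, which degrades gracefully to the
Jukes-Cantor closed form in the equal-frequency, kappa = 1 limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(BASES)}
# transition partners (A<->G, C<->T)
_TRANSITION = {(0, 2), (2, 0), (1, 3), (3, 1)}

D_MAX = 5.0
KAPPA_BOUNDS = (0.05, 100.0)


@dataclass(frozen=True)
class HkyParams:
    """Estimated (or planted) HKY85 parameters for one sequence pair."""

    d: float
    kappa: float
    pi: tuple[float, float, float, float]
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if abs(sum(self.pi) - 1.0) > 1e-6:
            raise ValueError("pi must sum to 1")


def rate_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    """HKY85 rate matrix scaled to one expected substitution per unit time."""
    pi = np.asarray(pi, dtype=float)
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = kappa if (i, j) in _TRANSITION else 1.0
            q[i, j] = rate * pi[j]
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(pi * np.diag(q)).sum()
    return q / mean_rate


def transition_matrix(d: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    """P(d) = exp(Q d) for the normalized HKY85 rate matrix."""
    if d == 0:
        return np.eye(4)
    return expm(rate_matrix(kappa, np.asarray(pi, dtype=float)) * d)


def evolve(seq: str, d: float, kappa: float, pi, rng: np.random.Generator) -> str:
    """Evolve a sequence for branch length d substitutions/site under HKY85.

    Sites are independent; N residues are carried through unchanged.
    """
    if d < 0:
        raise ValueError("branch length must be >= 0")
    p = transition_matrix(d, kappa, np.asarray(pi, dtype=float))
    idx = np.array([_INDEX.get(c, -1) for c in seq])
    out = np.array(list(seq))
    valid = idx >= 0
    if valid.any():
        u = rng.random(valid.sum())
        cum = np.cumsum(p[idx[valid]], axis=1)
        new_idx = (u[:, None] > cum).sum(axis=1)
        out[valid] = np.array(list(BASES))[new_idx]
    return "".join(out)


def _pair_counts(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    """4x4 site-pattern counts and pooled base counts; gap/N columns dropped."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    counts = np.zeros((4, 4))
    base_counts = np.zeros(4)
    for x, y in zip(a, b):
        i, j = _INDEX.get(x, -1), _INDEX.get(y, -1)
        if i < 0 or j < 0:
            continue
        counts[i, j] += 1
        base_counts[i] += 1
        base_counts[j] += 1
    return counts, base_counts


def _neg_log_likelihood(params: np.ndarray, counts: np.ndarray, pi: np.ndarray) -> float:
    d, kappa = params
    p = transition_matrix(max(d, 1e-9), kappa, pi)
    with np.errstate(divide="ignore"):
        logterm = np.log(np.maximum(pi[:, None] * p, 1e-300))
    return -(counts * logterm).sum()


def ml_distance(a: str, b: str) -> HkyParams:
    """Maximum-likelihood HKY85 distance for an aligned pair.

    Columns containing a gap or N are excluded.  Identical sequences return
    d = 0 exactly.  Estimates pinned at the upper branch-length bound are
    flagged ``saturated`` and should be excluded from age summaries.
    """
    counts, base_counts = _pair_counts(a, b)
    n = counts.sum()
    if n == 0:
        raise ValueError("no comparable (gap-free, unambiguous) columns")
    diffs = n - np.trace(counts)
    if diffs == 0:
        pi = base_counts / base_counts.sum()
        return HkyParams(0.0, 1.0, tuple(pi))
    pi = np.maximum(base_counts / base_counts.sum(), 1e-6)
    pi = pi / pi.sum()
    p_dist = diffs / n
    # Jukes-Cantor start point (capped below saturation).
    jc_arg = 1.0 - 4.0 * p_dist / 3.0
    d0 = -0.75 * np.log(jc_arg) if jc_arg > 0.02 else 2.0
    best = None
    for k0 in (1.0, 4.0):
        res = minimize(
            _neg_log_likelihood,
            x0=np.array([min(max(d0, 1e-4), D_MAX - 1e-3), k0]),
            args=(counts, pi),
            method="L-BFGS-B",
            bounds=[(1e-8, D_MAX), KAPPA_BOUNDS],
        )
        if best is None or res.fun < best.fun:
            best = res
    d_hat, kappa_hat = float(best.x[0]), float(best.x[1])
    saturated = d_hat >= D_MAX - 1e-2
    return HkyParams(d_hat, kappa_hat, tuple(pi), saturated=saturated)
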