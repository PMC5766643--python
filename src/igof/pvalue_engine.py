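"""Permutation p-values and the analytic screening approximations.

Three ingredients of the gene-pair tests live here:

* :func:`adaptive_permutation` — label-shuffling p-value estimation with
  early stopping: permutations stop once a preset number of exceedances
  ``r`` is reached (p = r/B) or the permutation budget ``b`` is exhausted
  (p = (R+1)/(b+1)).  Ties between permuted and observed statistics do not
  count as exceedances (strict ">").
* screening approximations ``p_N`` (tail of the sum of the k largest of n
  independent standard normals), ``p_D`` (chi-square tail at the summed
  category counts) and ``p_SW`` (Satterthwaite–Welch moment-matched scaled
  chi-square).  These gate whether the expensive permutation run happens at
  all; they are never reported as final p-values.
* :func:`two_stage_gate` — the elevated-threshold rule: permute only when
  the screening p-value falls below ``m * alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import chi2

__all__ = [
    "PermutationOutcome",
    "SwMoments",
    "DegenerateNullError",
    "adaptive_permutation",
    "estimate_br",
    "approx_p_common",
    "sum_top_k_normal_sf",
    "approx_p_lf_df",
    "satterthwaite_welch",
    "two_stage_gate",
]


class DegenerateNullError(ValueError):
    """Raised when permutation null draws carry no usable variance."""


@dataclass(frozen=True)
class PermutationOutcome:
    """Result of one adaptive permutation run.

    ``p = r/B`` when stopped early at the ``r``-th exceedance, otherwise
    ``(R+1)/(b+1)`` after the full budget.
    """

    p: float
    B: int  # permutations executed
    R: int  # exceedances observed
    stopped_early: bool


def adaptive_permutation(stat_fn, observed, labels, b, r, rng) -> PermutationOutcome:
    """Estimate a permutation p-value with early stopping.

    ``stat_fn`` maps a case/control label vector to a statistic; ``labels``
    is the observed label vector whose uniform shuffles form the null.
    Larger statistics mean stronger evidence; exceedance is strict
    (``permuted > observed``).
    """
    if not (b >= r >= 1):
        raise ValueError(f"require b >= r >= 1, got b={b}, r={r}")
    labels = np.asarray(labels)
    R = 0
    for i in range(1, b + 1):
        perm = rng.permutation(labels)
        try:
            s = stat_fn(perm)
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"stat_fn failed at permutation {i}") from e
        if s > observed:
            R += 1
            if R == r:
                return PermutationOutcome(p=r / i, B=i, R=R, stopped_early=True)
    return PermutationOutcome(p=(R + 1) / (b + 1), B=b, R=R, stopped_early=False)


def estimate_br(alpha, num_tests=None, se_fraction=0.2):
    """Adaptive-permutation budget ``(b, r)`` for significance level ``alpha``.

    Ships the published defaults — (2,500, 36) at the 1% level, (25,000, 36)
    at 0.1%, (1.25e8, 36) at 2e-7 — i.e. ``b`` scales as 25/alpha with ``r``
    fixed at 36, which keeps the standard error of the p-value estimate
    under ``se_fraction`` of ``alpha``.  ``num_tests`` is accepted for
    interface compatibility; the shipped rule does not depend on it.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    del num_tests, se_fraction
    return int(math.ceil(25.0 / alpha)), 36


# --------------------------------------------------------------------------
# p_N: tail of the sum of the k largest of n independent standard normals.
#
# The tail is evaluated from a cached Monte-Carlo table: for each pool size
# n (snapped to a geometric grid above 20) a fixed-seed simulation stores,
# for every k up to a cap, a compressed empirical distribution of the
# top-k sum (exact upper-tail values plus an evenly spaced quantile grid).
# The k = n case is exact (the full sum is Normal(0, n)) and anchors the
# table; for n > _ASYMPTOTIC_N an L-statistic normal approximation is used.
# --------------------------------------------------------------------------

_ASYMPTOTIC_N = 200
_EXACT_N = 20  # exact node for every n up to here
_GRID_RATIO = 1.08
_KMAX_STORE = 40
_TAIL_KEEP = 4096
_BULK_QUANTILES = 2048
_TABLE_SEED = 0x1607F


def _node_for(n: int, k: int) -> int:
    if n <= _EXACT_N:
        return n
    # snap to nearest geometric grid point, but never below k
    steps = round(math.log(n / _EXACT_N) / math.log(_GRID_RATIO))
    node = round(_EXACT_N * _GRID_RATIO ** steps)
    node = min(node, _ASYMPTOTIC_N)
    if node < k:
        return n
    return node


def _draws_for(n: int) -> int:
    # small pools back the precision-checked regime; larger pools only feed
    # the m*alpha gate, where modest Monte-Carlo error is immaterial
    return 400_000 if n <= 12 else 50_000


class _CompressedTail:
    """Empirical survival function of one top-k-sum sample."""

    __slots__ = ("B", "tail", "q_vals", "q_ranks")

    def __init__(self, sorted_sample: np.ndarray):
        B = sorted_sample.size
        self.B = B
        t = min(_TAIL_KEEP, B)
        self.tail = sorted_sample[B - t:]
        ranks = np.linspace(0, B - t, _BULK_QUANTILES).astype(np.int64)
        self.q_vals = sorted_sample[np.minimum(ranks, B - 1)]
        self.q_ranks = ranks.astype(np.float64)

    def sf(self, y: float) -> float:
        if y >= self.tail[0]:
            cnt = self.tail.size - np.searchsorted(self.tail, y, side="right")
            p = cnt / self.B
        else:
            rank = np.interp(y, self.q_vals, self.q_ranks)
            p = (self.B - rank) / self.B
        return float(min(1.0, max(p, 1.0 / (self.B + 1))))


_TOPK_TABLE: dict[tuple[int, int], _CompressedTail] = {}
_MATERIALIZED_NODES: set[int] = set()


def _materialize_node(node: int) -> None:
    """Simulate the top-k sums for one n-node and store all k <= cap."""
    B = _draws_for(node)
    kmax = min(node, _KMAX_STORE)
    rng = np.random.default_rng(np.random.SeedSequence((_TABLE_SEED, node)))
    acc = np.empty((B, kmax), dtype=np.float32)
    chunk = max(1, int(4_000_000 // max(node, 1)))
    done = 0
    while done < B:
        c = min(chunk, B - done)
        x = rng.standard_normal((c, node))
        x.sort(axis=1)
        top_desc = x[:, node - kmax:][:, ::-1]  # view of the k largest only
        acc[done:done + c] = np.cumsum(top_desc, axis=1)
        done += c
    for k in range(1, kmax + 1):
        col = np.sort(acc[:, k - 1].astype(np.float64))
        _TOPK_TABLE[(node, k)] = _CompressedTail(col)
    _MATERIALIZED_NODES.add(node)


def _topk_sf_montecarlo(y: float, node: int, k: int) -> float:
    key = (node, k)
    if key not in _TOPK_TABLE:
        if k <= min(node, _KMAX_STORE) and node not in _MATERIALIZED_NODES:
            _materialize_node(node)
        else:
            # k beyond the stored cap: one-off simulation for this pair
            B = 100_000
            rng = np.random.default_rng(np.random.SeedSequence((_TABLE_SEED, node, k)))
            out = np.empty(B, dtype=np.float64)
            chunk = max(1, int(4_000_000 // max(node, 1)))
            done = 0
            while done < B:
                c = min(chunk, B - done)
                x = rng.standard_normal((c, node))
                part = -np.partition(-x, k - 1, axis=1)[:, :k]
                out[done:done + c] = part.sum(axis=1)
                done += c
            _TOPK_TABLE[key] = _CompressedTail(np.sort(out))
    return _TOPK_TABLE[key].sf(y)


def _topk_sf_asymptotic(y: float, n: int, k: int) -> float:
    """L-statistic CLT for the trimmed upper sum, k/n bounded away from 0."""
    beta = k / n
    c = ndtri(1.0 - beta)
    phi_c = math.exp(-0.5 * c * c) / math.sqrt(2.0 * math.pi)
    mean = n * phi_c
    ez = phi_c + c * beta
    ez2 = beta + 3.0 * c * phi_c + c * c * beta
    var = n * max(ez2 - ez * ez, 1e-12)
    return float(ndtr(-(y - mean) / math.sqrt(var)))


def sum_top_k_normal_sf(y: float, n: int, k: int) -> float:
    """P(sum of the k largest of n iid standard normals > y)."""
    if not (n >= k >= 1):
        raise ValueError(f"require n >= k >= 1, got n={n}, k={k}")
    if k == n:
        return float(ndtr(-y / math.sqrt(n)))
    if n > _ASYMPTOTIC_N:
        return _topk_sf_asymptotic(y, n, k)
    return _topk_sf_montecarlo(y, _node_for(n, k), k)


def approx_p_common(i_common: float, n: int, k: int) -> float:
    """Screening p-value ``p_N`` for the common-pair statistic.

    Approximates the upper tail of the sum of the ``k`` largest of ``n``
    independent standard normals at ``i_common``; correlations between
    variant pairs make this an approximation, so it only gates the
    permutation run.
    """
    return sum_top_k_normal_sf(i_common, n, k)


def approx_p_lf_df(i_lf: float, total_df: int) -> float:
    """Screening p-value ``p_D``: chi-square tail of I_LF at the summed
    non-zero-category counts of the selected pairs.  Anti-conservative by
    construction (selection bias, correlation, sparse tables) — gate only.
    """
    if total_df < 1:
        raise ValueError("total_df must be >= 1")
    return float(chi2.sf(i_lf, total_df))


@dataclass(frozen=True)
class SwMoments:
    """Moment-matched scaled chi-square ``g * chi2_h``.

    ``k1``/``k2`` are the first moment and second central moment of the
    null statistic; ``g = k2 / (2 k1)`` and ``h = 2 k1^2 / k2``.
    """

    k1: float
    k2: float

    @property
    def g(self) -> float:
        return self.k2 / (2.0 * self.k1)

    @property
    def h(self) -> float:
        return 2.0 * self.k1 ** 2 / self.k2

    @classmethod
    def from_draws(cls, draws) -> "SwMoments":
        draws = np.asarray(draws, dtype=np.float64)
        if draws.size < 2:
            raise ValueError("need at least two null draws")
        k1 = float(draws.mean())
        k2 = float(draws.var(ddof=1))
        if k2 <= 0.0 or k1 <= 0.0:
            raise DegenerateNullError("null draws have zero mean or variance")
        return cls(k1=k1, k2=k2)

    def sf(self, x: float) -> float:
        return float(chi2.sf(x / self.g, self.h))


def satterthwaite_welch(i_lf: float, null_draws) -> float:
    """Screening p-value ``p_SW`` from permuted null statistics.

    Fits a scaled chi-square to the empirical mean and variance of the
    permuted I_LF values and evaluates its upper tail at the observed
    statistic.  Raises :class:`DegenerateNullError` when the draws carry no
    variance (callers fall back to plain permutation).
    """
    return SwMoments.from_draws(null_draws).sf(i_lf)


def two_stage_gate(approx_p: float, m: float, alpha: float) -> bool:
    """Proceed to permutation iff the screening p-value beats ``m * alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m <= 0:
        raise ValueError("m must be positive")
    return approx_p < m * alpha
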