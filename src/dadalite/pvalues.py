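"""The two tail statistics that decide sequences are not errors.

*Abundance p-value* ``p_y``: given that a family was seen at all, the
probability of seeing at least as many reads of it as were observed, with the
read count binomial ``Bin(rho, lambda)`` (rho = cluster reads, lambda = the
family's per-read error probability).  Small p_y = too many reads to be
errors.  Any singleton family (r_y = 1) gets p_y = 1, which is why the second
statistic exists.

*Read p-value* ``q_alpha``: the probability that at least one of rho reads is
at least as improbable as the least probable observed family.  The tail over
all possible error sequences is organised by 4x4 off-diagonal count matrices
``gamma`` (how many i->j substitutions a sequence carries): all sequences of
type gamma share ``lambda = lambda_0 * lambda_gamma`` and are counted by an
exact multinomial degeneracy ``m_gamma``.  The sum over gamma above the
threshold is generated best-first, from common error combinations to rare
ones.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.stats import binom

from .error_model import BaseComposition, TransitionMatrix, log_no_error_probability

#: the 12 off-diagonal (i, j) index pairs, row-major
OFF_DIAGONAL = tuple((i, j) for i in range(4) for j in range(4) if i != j)


class EnumerationBudgetError(RuntimeError):
    """Raised when the gamma enumeration exceeds its expansion budget."""

    def __init__(self, reached_bound: float, budget: int):
        super().__init__(
            f"gamma enumeration budget of {budget} expansions exceeded; "
            f"reached lambda_gamma bound {reached_bound:.3e} "
            "(consider relaxing Omega_r)"
        )
        self.reached_bound = reached_bound
        self.budget = budget


@dataclass(frozen=True)
class GammaMatrix:
    """Off-diagonal 4x4 substitution counts classifying an error sequence."""

    counts: Tuple[int, ...]  # 12 entries in OFF_DIAGONAL order

    def __post_init__(self):
        if len(self.counts) != 12:
            raise ValueError("GammaMatrix needs 12 off-diagonal counts")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")

    @classmethod
    def zero(cls) -> "GammaMatrix":
        return cls((0,) * 12)

    @classmethod
    def from_matrix(cls, mat) -> "GammaMatrix":
        mat = np.asarray(mat)
        if np.diag(mat).any():
            raise ValueError("gamma diagonal must be zero")
        return cls(tuple(int(mat[i, j]) for i, j in OFF_DIAGONAL))

    def as_matrix(self) -> np.ndarray:
        out = np.zeros((4, 4), dtype=int)
        for (i, j), c in zip(OFF_DIAGONAL, self.counts):
            out[i, j] = c
        return out

    @property
    def total_errors(self) -> int:
        return sum(self.counts)

    def row_sums(self) -> Tuple[int, int, int, int]:
        sums = [0, 0, 0, 0]
        for (i, _j), c in zip(OFF_DIAGONAL, self.counts):
            sums[i] += c
        return tuple(sums)


def abundance_pvalue(r_y: int, lam: float, rho: int) -> float:
    """P(R >= r_y | R >= 1) for R ~ Binomial(rho, lambda).

    Computed with the regularized-incomplete-beta survival function and
    ``expm1``/``log1p`` for the conditioning term, so it stays accurate for
    lambda down to ~1e-8 and rho up to ~1e6.
    """
    if not (1 <= r_y <= rho):
        raise ValueError(f"require 1 <= r_y <= rho, got r_y={r_y}, rho={rho}")
    if not (0.0 < lam < 1.0):
        raise ValueError(f"lambda must lie in (0, 1), got {lam}")
    if r_y == 1:
        return 1.0
    numerator = float(binom.sf(r_y - 1, rho, lam))
    # P(R >= 1); guard against underflow for lambda below ~1e-300
    denominator = max(-math.expm1(rho * math.log1p(-lam)), 5e-324)
    return min(numerator / denominator, 1.0)


def gamma_degeneracy(gamma: GammaMatrix, comp: BaseComposition) -> int:
    """Number of distinct sequences of error type gamma on a genotype.

    ``m_gamma = prod_i n_i! / ((n_i - sum_j gamma_ij)! prod_j gamma_ij!)``,
    in exact integer arithmetic.  Returns 0 when gamma is infeasible for the
    composition (more errors from base i than there are i's).
    """
    row = gamma.row_sums()
    m = 1
    for i in range(4):
        n_i = comp.counts[i]
        if row[i] > n_i:
            return 0
        coeff = math.factorial(n_i) // math.factorial(n_i - row[i])
        for (ri, _j), c in zip(OFF_DIAGONAL, gamma.counts):
            if ri == i and c:
                coeff //= math.factorial(c)
        m *= coeff
    return m


def lambda_gamma(gamma: GammaMatrix, T: TransitionMatrix) -> float:
    """lambda_gamma = prod_{i != j} (T_ij / T_ii)^gamma_ij (genotype-independent)."""
    log_lg = 0.0
    for (i, j), c in zip(OFF_DIAGONAL, gamma.counts):
        if c:
            log_lg += c * (T.log_probs[i, j] - T.log_probs[i, i])
    return math.exp(log_lg)


def read_pvalue(
    lambda_star: float,
    rho: int,
    comp: BaseComposition,
    T: TransitionMatrix,
    max_expansions: int = 10_000_000,
    stop_below: float | None = None,
) -> float:
    """q = P(at least one of rho reads has lambda <= lambda_star).

    ``q = 1 - (lambda_0 * sum_{gamma : lambda_gamma > lambda_star/lambda_0}
    m_gamma lambda_gamma) ** rho``.  The gamma sum is generated best-first
    (largest lambda_gamma popped first from a priority queue, each gamma's
    single-error extensions pushed, duplicates merged), which enumerates every
    gamma above the threshold because extensions only lower lambda_gamma.

    Every popped partial sum yields an upper bound on q that decreases
    monotonically; if ``stop_below`` is given and the bound drops under it,
    that bound is returned early (sufficient to decide significance against a
    threshold >= ``stop_below``).  If neither completion nor the early stop is
    reached within ``max_expansions`` pops, :class:`EnumerationBudgetError`
    is raised.
    """
    if rho < 1:
        raise ValueError("rho must be >= 1")
    if lambda_star <= 0.0:
        raise ValueError("lambda_star must be positive")
    log_lam0 = log_no_error_probability(comp, T)
    lam0 = math.exp(log_lam0)
    if lambda_star > lam0:
        raise ValueError("lambda_star cannot exceed the no-error probability")
    threshold = lambda_star / lam0  # compare lambda_gamma > threshold (strict)

    ratios = [math.exp(T.log_probs[i, j] - T.log_probs[i, i]) for i, j in OFF_DIAGONAL]
    n_by_row = comp.counts

    start = (0,) * 12
    heap = [(-1.0, start)]  # (-lambda_gamma, counts)
    best_lg = {start: 1.0}
    popped = set()
    S = 0.0  # sum of m_gamma * lambda_gamma over gammas above threshold
    expansions = 0
    last_lg = 1.0

    def q_bound(s: float) -> float:
        if s <= 0.0:
            return 1.0
        inner = log_lam0 + math.log(s)
        if inner >= 0.0:
            return 0.0
        return -math.expm1(rho * inner)

    while heap:
        neg_lg, counts = heapq.heappop(heap)
        if counts in popped:
            continue
        popped.add(counts)
        lg = -neg_lg
        last_lg = lg
        if lg <= threshold:
            break  # everything still queued is no larger: enumeration complete
        g = GammaMatrix(counts)
        m = gamma_degeneracy(g, comp)
        if m:
            S += m * lg
        expansions += 1
        if stop_below is not None and expansions % 64 == 0 and q_bound(S) < stop_below:
            return q_bound(S)
        if expansions >= max_expansions:
            if stop_below is not None and q_bound(S) < stop_below:
                return q_bound(S)
            raise EnumerationBudgetError(lg, max_expansions)
        row = g.row_sums()
        for k, (i, _j) in enumerate(OFF_DIAGONAL):
            if row[i] + 1 > n_by_row[i]:
                continue  # infeasible in this row, and stays infeasible
            child = counts[:k] + (counts[k] + 1,) + counts[k + 1:]
            child_lg = lg * ratios[k]
            if child not in popped and child_lg > best_lg.get(child, -1.0):
                best_lg[child] = child_lg
                heapq.heappush(heap, (-child_lg, child))
    return min(max(q_bound(S), 0.0), 1.0)


def bonferroni_test(
    p_values: Sequence[float],
    omega: float,
    n_tests: int,
    tie_keys: Sequence[tuple] | None = None,
) -> tuple[bool, int]:
    """Bonferroni-corrected joint test: pass iff min p >= omega / n_tests.

    Returns ``(passed, worst_index)`` where the worst index is the argmin;
    ties are broken by ``tie_keys`` when given (sorted ascending, so supply
    e.g. ``(-reads, sequence)`` to prefer the most abundant family).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if len(p_values) == 0:
        raise ValueError("empty p-value list")
    if tie_keys is None:
        tie_keys = [(i,) for i in range(len(p_values))]
    order = sorted(range(len(p_values)), key=lambda i: (p_values[i], tuple(tie_keys[i])))
    worst = order[0]
    return p_values[worst] >= omega / n_tests, worst
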