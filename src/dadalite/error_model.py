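"""Nucleotide substitution-error probabilities and their maximum-likelihood estimation.

The error process is a homogeneous per-site model: a sample base ``i`` is read
as base ``j`` with probability ``T[i, j]``, independently across sites and
across reads.  ``T`` is a 4x4 row-stochastic matrix over (A, C, G, T); the
context-dependent variant keeps one such matrix per pair of flanking genotype
nucleotides (16 contexts x 12 free rates = 192 parameters).

The probability that errors convert a genotype into a particular read (the
genotype error probability, lambda) is the product of the per-site transition
probabilities over the aligned, non-gap columns; indels contribute no factor.

Given a partition of reads into clusters with inferred genotypes, the MLE of
each off-diagonal rate is the read-weighted count of genotype-``i`` positions
read as ``j`` divided by all genotype-``i`` positions; diagonals follow by row
normalization.  Zero counts are floored (see :meth:`TransitionMatrix.from_counts`)
so that log-scores and lambdas stay finite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_ROW_SUM_TOL = 1e-12

# absolute lower bound for any off-diagonal rate; the count-scaled floor
# max(1/(N_i+1), ABS_FLOOR) can only raise it
ABS_FLOOR = 1e-8


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 index array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = _ENCODE_LUT[arr]
    if (out < 0).any():
        raise ValueError("sequence contains non-ACGT symbols")
    return out


_ENCODE_LUT = np.full(128, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i


class TransitionMatrix:
    """4x4 row-stochastic nucleotide error probabilities, P(read j | sample i).

    Parameters
    ----------
    probs : array-like, shape (4, 4)
        Row-stochastic; every entry in (0, 1); each diagonal entry must
        exceed every off-diagonal entry in its row.
    floor : float
        Smallest admissible off-diagonal probability.
    """

    def __init__(self, probs, floor: float = ABS_FLOOR):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (4, 4):
            raise ValueError("TransitionMatrix must be 4x4")
        if not np.allclose(probs.sum(axis=1), 1.0, rtol=0, atol=_ROW_SUM_TOL):
            raise ValueError("rows must sum to 1 within 1e-12")
        if not ((probs > 0) & (probs < 1)).all():
            raise ValueError("all entries must lie strictly in (0, 1)")
        off = probs[~np.eye(4, dtype=bool)].reshape(4, 3)
        if not (np.diag(probs)[:, None] > off).all():
            raise ValueError("diagonal entries must dominate their row")
        if (off < floor * (1 - 1e-9)).any():
            raise ValueError(f"off-diagonal entries must be >= floor ({floor})")
        self.probs = probs
        self.floor = floor
        self.log_probs = np.log(probs)

    def __getitem__(self, key):
        return self.probs[key]

    def __repr__(self):  # pragma: no cover
        return f"TransitionMatrix({np.array_str(self.probs, precision=4)})"

    def max_abs_difference(self, other: "TransitionMatrix") -> float:
        return float(np.abs(self.probs - other.probs).max())

    @classmethod
    def uniform(cls, off_diagonal: float = 1e-3) -> "TransitionMatrix":
        """All twelve off-diagonal rates equal; used as the provisional model."""
        probs = np.full((4, 4), off_diagonal)
        np.fill_diagonal(probs, 1.0 - 3 * off_diagonal)
        return cls(probs, floor=min(off_diagonal, ABS_FLOOR))

    @classmethod
    def from_counts(cls, counts, warn: bool = True) -> "TransitionMatrix":
        """MLE from a 4x4 count matrix: T_ij = N_ij / N_i, diagonal by normalization.

        Off-diagonals are floored at ``max(1/(N_i + 1), 1e-8)`` and the diagonal
        re-set by normalization, so that zero observed counts never produce a
        zero rate.  A row with no observations at all (N_i = 0) falls back to
        off-diagonals at the absolute floor, with a warning.
        """
        counts = np.asarray(counts, dtype=float)
        probs = np.empty((4, 4))
        for i in range(4):
            n_i = counts[i].sum()
            if n_i <= 0:
                if warn:
                    warnings.warn(
                        f"no aligned positions for genotype base {BASES[i]}; "
                        "row set to floor default",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                row_floor = ABS_FLOOR
                off = np.full(4, row_floor)
            else:
                row_floor = max(1.0 / (n_i + 1.0), ABS_FLOOR)
                off = np.maximum(counts[i] / n_i, row_floor)
            off[i] = 0.0
            probs[i] = off
            probs[i, i] = 1.0 - off.sum()
        return cls(probs)


@dataclass
class ContextTransitionMatrix:
    """Nearest-neighbor context-dependent error probabilities.

    One :class:`TransitionMatrix` per (L, R) pair of flanking genotype
    nucleotides, plus a context-independent fallback used at sequence termini
    and next to alignment gaps.
    """

    matrices: dict  # (L, R) base pair -> TransitionMatrix
    fallback: TransitionMatrix

    N_CONTEXTS = 16
    N_FREE_PARAMETERS = 192  # 16 contexts x 12 free rates

    def __post_init__(self):
        if len(self.matrices) != self.N_CONTEXTS:
            raise ValueError("expected one matrix per (L, R) context (16)")

    def matrix_for(self, left: str | None, right: str | None) -> TransitionMatrix:
        if left is None or right is None:
            return self.fallback
        return self.matrices[(left, right)]

    @classmethod
    def from_counts(
        cls,
        context_counts: np.ndarray,
        fallback: TransitionMatrix,
        warn: bool = True,
    ) -> "ContextTransitionMatrix":
        """Per-context MLE from a (4, 4, 4, 4) array indexed [L, R, i, j].

        Rows without any observations in a context inherit the fallback
        (context-independent) row, with a warning.
        """
        context_counts = np.asarray(context_counts, dtype=float)
        matrices = {}
        for li in range(4):
            for ri in range(4):
                counts = context_counts[li, ri]
                probs = np.empty((4, 4))
                missing = []
                for i in range(4):
                    n = counts[i].sum()
                    if n <= 0:
                        probs[i] = fallback.probs[i]
                        missing.append(BASES[i])
                    else:
                        row_floor = max(1.0 / (n + 1.0), ABS_FLOOR)
                        off = np.maximum(counts[i] / n, row_floor)
                        off[i] = 0.0
                        probs[i] = off
                        probs[i, i] = 1.0 - off.sum()
                if missing and warn:
                    logger.warning(
                        "context (%s,%s): no observations for genotype base(s) %s; "
                        "using context-independent rates",
                        BASES[li],
                        BASES[ri],
                        ",".join(missing),
                    )
                matrices[(BASES[li], BASES[ri])] = TransitionMatrix(probs)
        return cls(matrices=matrices, fallback=fallback)


@dataclass(frozen=True)
class BaseComposition:
    """Nucleotide counts of a genotype: n_i for i in (A, C, G, T)."""

    counts: Tuple[int, int, int, int]

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")
        if self.length == 0:
            raise ValueError("composition length must be positive")

    @property
    def length(self) -> int:
        return sum(self.counts)

    @classmethod
    def from_sequence(cls, seq: str) -> "BaseComposition":
        idx = encode(seq)
        return cls(tuple(int(np.sum(idx == i)) for i in range(4)))


# ---------------------------------------------------------------------------
# Genotype error probabilities (lambda)
# ---------------------------------------------------------------------------


def log_genotype_error_probability(alignment, T) -> float:
    """log lambda: sum of per-site log transition probabilities over non-gap columns.

    ``alignment`` is a :class:`~dadalite.align.PairwiseAlignment`.  With a
    context-dependent ``T`` the flanking bases are the genotype's own
    neighbors of each position; terminal positions use the fallback rates.
    """
    g_idx, y_idx, g_pos, _ = alignment.index_arrays()
    if isinstance(T, TransitionMatrix):
        return float(T.log_probs[g_idx, y_idx].sum())
    # context-dependent: group by flanking genotype bases
    geno = alignment.genotype_indices()
    L = len(geno)
    total = 0.0
    for gi, yi, p in zip(g_idx, y_idx, g_pos):
        if p == 0 or p == L - 1:
            total += T.fallback.log_probs[gi, yi]
        else:
            mat = T.matrices[(BASES[geno[p - 1]], BASES[geno[p + 1]])]
            total += mat.log_probs[gi, yi]
    return total


def genotype_error_probability(alignment, T) -> float:
    """lambda = product of T[genotype base -> read base] over aligned non-gap columns.

    Gap columns contribute no factor (indels are not modeled).
    """
    return float(np.exp(log_genotype_error_probability(alignment, T)))


def no_error_probability(comp: BaseComposition, T) -> float:
    """lambda_0: probability of reading a genotype with zero substitutions.

    ``lambda_0 = prod_i T_ii ** n_i``.  With context-dependent rates the
    genotype sequence itself is needed; pass a TransitionMatrix here (the
    read p-value is always computed context-independently).
    """
    if not isinstance(T, TransitionMatrix):
        raise TypeError("no_error_probability expects a context-independent matrix")
    return float(np.exp(log_no_error_probability(comp, T)))


def log_no_error_probability(comp: BaseComposition, T: TransitionMatrix) -> float:
    return float(np.dot(np.asarray(comp.counts, dtype=float), np.diag(T.log_probs)))


# ---------------------------------------------------------------------------
# Maximum-likelihood estimation from aligned partitions
# ---------------------------------------------------------------------------


def tally_substitutions(aligned_pairs: Iterable[tuple]) -> np.ndarray:
    """Read-weighted 4x4 substitution counts N_ij from (alignment, weight) pairs.

    Every aligned non-gap column of every unique sequence contributes its read
    multiplicity to ``N[genotype base, read base]``.
    """
    counts = np.zeros((4, 4))
    for alignment, weight in aligned_pairs:
        g_idx, y_idx, _, _ = alignment.index_arrays()
        np.add.at(counts, (g_idx, y_idx), float(weight))
    return counts


def tally_context_substitutions(
    aligned_pairs: Iterable[tuple],
) -> tuple[np.ndarray, np.ndarray]:
    """Context-resolved counts: (N[L, R, i, j], boundary N[i, j]).

    Positions at a genotype terminus or whose neighboring alignment column is
    a gap are tallied into the boundary (context-independent) pool.
    """
    ctx = np.zeros((4, 4, 4, 4))
    boundary = np.zeros((4, 4))
    for alignment, weight in aligned_pairs:
        g_idx, y_idx, g_pos, interior = alignment.index_arrays()
        geno = alignment.genotype_indices()
        w = float(weight)
        if interior.any():
            gi = g_idx[interior]
            yi = y_idx[interior]
            pp = g_pos[interior]
            np.add.at(ctx, (geno[pp - 1], geno[pp + 1], gi, yi), w)
        if (~interior).any():
            np.add.at(boundary, (g_idx[~interior], y_idx[~interior]), w)
    return ctx, boundary


def estimate_T_mle(aligned_pairs: Iterable[tuple], warn: bool = True) -> TransitionMatrix:
    """Context-independent MLE of T from an aligned partition.

    ``aligned_pairs`` yields ``(PairwiseAlignment, read_weight)`` with every
    unique sequence aligned to its cluster genotype.
    """
    return TransitionMatrix.from_counts(tally_substitutions(aligned_pairs), warn=warn)


def estimate_T_context_mle(
    aligned_pairs: Iterable[tuple], warn: bool = True
) -> ContextTransitionMatrix:
    """Context-dependent MLE: one matrix per (L, R) flanking pair.

    Boundary positions (termini, gap-adjacent) are pooled with all positions
    into the context-independent fallback estimate.
    """
    aligned_pairs = list(aligned_pairs)
    ctx, _boundary = tally_context_substitutions(aligned_pairs)
    fallback = estimate_T_mle(aligned_pairs, warn=warn)
    return ContextTransitionMatrix.from_counts(ctx, fallback, warn=warn)


# ---------------------------------------------------------------------------
# Complement symmetry diagnostic
# ---------------------------------------------------------------------------


def complement_symmetry_pairs(T) -> list[tuple[str, float, str, float]]:
    """Pair each substitution error with its reverse-complement error.

    Substitution errors arising during PCR share mis-pairing events with their
    complement (an A->G on one strand is a T->C on the other), so the two
    rates are expected to be similar even though the estimator never imposes
    it.  Returns 6 pairs for a context-independent matrix and 96 for a
    context-dependent one; the first label of each pair is the error away
    from an A or C.
    """
    pairs = []
    if isinstance(T, TransitionMatrix):
        for i in "AC":
            for j in BASES:
                if j == i:
                    continue
                ci, cj = COMPLEMENT[i], COMPLEMENT[j]
                pairs.append(
                    (
                        f"{i}->{j}",
                        float(T.probs[BASE_INDEX[i], BASE_INDEX[j]]),
                        f"{ci}->{cj}",
                        float(T.probs[BASE_INDEX[ci], BASE_INDEX[cj]]),
                    )
                )
        return pairs
    if isinstance(T, ContextTransitionMatrix):
        for left in BASES:
            for right in BASES:
                for i in "AC":
                    for j in BASES:
                        if j == i:
                            continue
                        # reverse complement of LiR is rc(R) rc(i) rc(L)
                        cl, cr = COMPLEMENT[right], COMPLEMENT[left]
                        ci, cj = COMPLEMENT[i], COMPLEMENT[j]
                        p1 = T.matrices[(left, right)].probs[BASE_INDEX[i], BASE_INDEX[j]]
                        p2 = T.matrices[(cl, cr)].probs[BASE_INDEX[ci], BASE_INDEX[cj]]
                        pairs.append(
                            (
                                f"{left}{i}{right}->{left}{j}{right}",
                                float(p1),
                                f"{cl}{ci}{cr}->{cl}{cj}{cr}",
                                float(p2),
                            )
                        )
        return pairs
    raise TypeError(f"unsupported matrix type: {type(T)!r}")


def error_rates_payload(T: TransitionMatrix, T_context: ContextTransitionMatrix | None = None) -> dict:
    """JSON-serializable error-rate summary (row/column order ACGT)."""
    payload = {"context_independent": T.probs.tolist()}
    if T_context is not None:
        payload["context_dependent"] = {
            f"{l}_{r}": m.probs.tolist() for (l, r), m in T_context.matrices.items()
        }
    return payload
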