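"""Coarse single-linkage preclustering at 3% substitution distance.

The probabilistic clustering runs independently inside each precluster:
error-containing reads are essentially always chained to their source
genotype (a gap of >3% inside an error cloud is wildly improbable), so this
is a safe and large speedup.  Indels do not contribute to the distance.

An ESPRIT-style k-mer screen provides a cheap lower-bound proxy so that the
quadratic all-pairs alignment is only performed on candidate pairs; a
union-find over candidate edges skips alignments between sequences already
connected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from . import align as _align
from .error_model import TransitionMatrix, encode
from .seqio import ReadSet, UniqueSequence

DEFAULT_CUTOFF = 0.03
#: slack on the k-mer proxy: candidate pairs are those with proxy <= this.
#: A pair at true substitution distance d can lose at most ~k*d*L k-mers, so
#: 0.5 is far above anything a <=3% pair can reach (validated in tests).
DEFAULT_SCREEN_SLACK = 0.5
DEFAULT_K = 6

#: provisional uniform error rate for the distance score matrix, used before
#: any data-driven estimate of T exists
PROVISIONAL_OFF_DIAGONAL = 1e-3


@dataclass
class Precluster:
    """A connected component of the <= cutoff substitution-distance graph."""

    id: int
    members: list[UniqueSequence]

    @property
    def total_reads(self) -> int:
        return sum(m.abundance for m in self.members)


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    idx = encode(seq).astype(np.int64)
    if len(idx) < k:
        raise ValueError(f"sequence shorter than k={k}")
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return np.lib.stride_tricks.sliding_window_view(idx, k) @ powers


def _kmer_profile(seq: str, k: int) -> np.ndarray:
    """Sorted distinct k-mer codes (base-4 encoding)."""
    return np.unique(_kmer_codes(seq, k))


def kmer_screen_distance(s1: str, s2: str, k: int = DEFAULT_K) -> float:
    """1 - (shared k-mers) / (min length - k + 1): a fast distance lower bound.

    Shared k-mers are counted with multiplicity (the min of the two counts
    per k-mer), so identical sequences are at distance 0.
    """
    c1, n1 = np.unique(_kmer_codes(s1, k), return_counts=True)
    c2, n2 = np.unique(_kmer_codes(s2, k), return_counts=True)
    common, i1, i2 = np.intersect1d(c1, c2, assume_unique=True, return_indices=True)
    shared = int(np.minimum(n1[i1], n2[i2]).sum())
    denom = min(len(s1), len(s2)) - k + 1
    return 1.0 - shared / denom


def substitution_distance(s1: str, s2: str, scores: np.ndarray | None = None) -> float:
    """Fraction of aligned non-gap columns where the bases differ.

    Gap columns are excluded from both numerator and denominator, so
    sequences differing only by indels are at distance 0.
    """
    if scores is None:
        scores = _align.score_matrix_from_T(
            TransitionMatrix.uniform(PROVISIONAL_OFF_DIAGONAL)
        )
    aln = _align.needleman_wunsch(s1, s2, scores)
    n_cols = len(aln.genotype_aligned) - aln.n_gap_columns
    if n_cols == 0:
        return 0.0
    return len(aln.substitutions) / n_cols


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def single_linkage_preclusters(
    readset: ReadSet,
    cutoff: float = DEFAULT_CUTOFF,
    k: int = DEFAULT_K,
    screen_slack: float = DEFAULT_SCREEN_SLACK,
    scores: np.ndarray | None = None,
    use_screen: bool = True,
) -> list[Precluster]:
    """Connected components of the graph with edges at substitution distance <= cutoff.

    Candidate pairs come from the k-mer screen (proxy <= ``screen_slack``)
    and are processed in order of increasing proxy; pairs whose endpoints are
    already connected skip the alignment.  The result is independent of input
    order (components are), and is returned largest-total-reads first.
    """
    members = list(readset.members)
    n = len(members)
    if n == 0:
        raise ValueError("empty ReadSet")
    if scores is None:
        scores = _align.score_matrix_from_T(
            TransitionMatrix.uniform(PROVISIONAL_OFF_DIAGONAL)
        )
    uf = _UnionFind(n)
    if n > 1:
        pairs = _candidate_pairs(members, k, screen_slack) if use_screen else [
            (0.0, i, j) for i in range(n) for j in range(i + 1, n)
        ]
        for _proxy, i, j in sorted(pairs):
            if uf.find(i) == uf.find(j):
                continue
            if substitution_distance(members[i].sequence, members[j].sequence, scores) <= cutoff:
                uf.union(i, j)
    groups: dict[int, list[UniqueSequence]] = {}
    for i, m in enumerate(members):
        groups.setdefault(uf.find(i), []).append(m)
    comps = sorted(
        groups.values(),
        key=lambda ms: (-sum(m.abundance for m in ms), min(m.sequence for m in ms)),
    )
    return [
        Precluster(id=c, members=sorted(ms, key=lambda m: (-m.abundance, m.sequence)))
        for c, ms in enumerate(comps)
    ]


def _candidate_pairs(members, k: int, screen_slack: float):
    """(proxy, i, j) for pairs passing the k-mer screen, via a sparse product."""
    n = len(members)
    lengths = np.array([len(m.sequence) for m in members])
    rows, cols = [], []
    for i, m in enumerate(members):
        codes = _kmer_profile(m.sequence, k)
        rows.append(np.full(codes.size, i, dtype=np.int64))
        cols.append(codes)
    mat = sparse.csr_matrix(
        (np.ones(sum(r.size for r in rows), dtype=np.int32),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, 4 ** k),
    )
    shared = (mat @ mat.T).tocoo()
    out = []
    for i, j, s in zip(shared.row, shared.col, shared.data):
        if i >= j:
            continue
        denom = min(lengths[i], lengths[j]) - k + 1
        proxy = 1.0 - s / denom
        if proxy <= screen_slack:
            out.append((proxy, int(i), int(j)))
    return out
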