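"""Global alignment of reads to candidate genotypes, and indel families.

Alignments use a score matrix derived from the current error probabilities
(``5 + ln T``, comparable to BLAST's NUC.4.4), a linear gap penalty of -4 and
a reduced homopolymer gap penalty of -1.  A gap column counts as a
homopolymer gap when the base opposite the gap equals that strand's two
preceding bases, i.e. the indel modifies a run of at least three identical
nucleotides -- the dominant 454 indel mode.  Requiring a genuine run keeps
the cheap gap pair from masquerading as a rare substitution at two-base run
junctions, which would otherwise bias the error-rate estimates downward.

Because indels are not modeled probabilistically, reads in a cluster are
collapsed by their *substitution signature* (the set of substitutions seen
against the genotype, in ungapped genotype coordinates): reads differing only
in indel placement form one *indel family*, the unit on which the abundance
p-value is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from numba import njit

from .error_model import (
    BASES,
    TransitionMatrix,
    encode,
    log_no_error_probability,
    BaseComposition,
)

GAP = "-"
DEFAULT_GAP_PENALTY = -4.0
DEFAULT_HOMOPOLYMER_GAP_PENALTY = -1.0

#: traceback codes
_DIAG, _UP, _LEFT = 0, 1, 2


def score_matrix_from_T(T: TransitionMatrix) -> np.ndarray:
    """Score matrix 5 + ln(T): diagonal ~5, worst mismatches around -6."""
    return 5.0 + T.log_probs


@njit(cache=True)
def _nw_fill(g, y, scores, gap, hp_gap):
    """Fill DP and traceback matrices.

    Tie-break preference diagonal > up (gap in read) > left (gap in genotype);
    terminal gaps are charged like internal ones.  A gap is a homopolymer gap
    iff the base opposite it equals that strand's two preceding bases, i.e.
    the indel modifies a run of length >= 3 (the regime where pyrosequencer
    homopolymer slippage actually occurs): for a gap in the read at genotype
    position i-1, g[i-1]==g[i-2]==g[i-3]; for a gap in the genotype at read
    position j-1, y[j-1]==y[j-2]==y[j-3].
    """
    m = g.shape[0]
    n = y.shape[0]
    F = np.empty((m + 1, n + 1), dtype=np.float64)
    P = np.zeros((m + 1, n + 1), dtype=np.uint8)
    F[0, 0] = 0.0
    for i in range(1, m + 1):
        pen = hp_gap if (i >= 3 and g[i - 1] == g[i - 2] == g[i - 3]) else gap
        F[i, 0] = F[i - 1, 0] + pen
        P[i, 0] = _UP
    for j in range(1, n + 1):
        pen = hp_gap if (j >= 3 and y[j - 1] == y[j - 2] == y[j - 3]) else gap
        F[0, j] = F[0, j - 1] + pen
        P[0, j] = _LEFT
    for i in range(1, m + 1):
        up_pen = hp_gap if (i >= 3 and g[i - 1] == g[i - 2] == g[i - 3]) else gap
        for j in range(1, n + 1):
            left_pen = hp_gap if (j >= 3 and y[j - 1] == y[j - 2] == y[j - 3]) else gap
            best = F[i - 1, j - 1] + scores[g[i - 1], y[j - 1]]
            code = _DIAG
            up = F[i - 1, j] + up_pen
            if up > best:
                best = up
                code = _UP
            left = F[i, j - 1] + left_pen
            if left > best:
                best = left
                code = _LEFT
            F[i, j] = best
            P[i, j] = code
    return F[m, n], P


@dataclass
class PairwiseAlignment:
    """A global alignment of a read to a (putative) genotype.

    ``substitutions`` lists ``(genotype_position, from_base, to_base)`` for
    every non-gap column where the bases differ, with positions 0-based on
    the ungapped genotype.
    """

    genotype_aligned: str
    read_aligned: str
    score: float
    substitutions: list = field(default_factory=list)
    n_gap_columns: int = 0
    _arrays: tuple | None = field(default=None, repr=False, compare=False)
    _geno_idx: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.genotype_aligned) != len(self.read_aligned):
            raise ValueError("aligned strings must have equal length")
        for a, b in zip(self.genotype_aligned, self.read_aligned):
            if a == GAP and b == GAP:
                raise ValueError("column gapped in both strands")

    @property
    def genotype(self) -> str:
        return self.genotype_aligned.replace(GAP, "")

    @property
    def read(self) -> str:
        return self.read_aligned.replace(GAP, "")

    def genotype_indices(self) -> np.ndarray:
        if self._geno_idx is None:
            self._geno_idx = encode(self.genotype)
        return self._geno_idx

    def index_arrays(self):
        """Per non-gap column: genotype base, read base, genotype position, interiority.

        ``interior`` marks columns usable for context tallies: the genotype
        position is not a terminus and neither neighboring alignment column
        is a gap column.
        """
        if self._arrays is None:
            ga = self.genotype_aligned
            ra = self.read_aligned
            ncol = len(ga)
            g_idx, y_idx, g_pos, interior = [], [], [], []
            L = len(self.genotype)
            gp = -1
            for c in range(ncol):
                a, b = ga[c], ra[c]
                if a != GAP:
                    gp += 1
                if a == GAP or b == GAP:
                    continue
                g_idx.append(ord(a))
                y_idx.append(ord(b))
                g_pos.append(gp)
                ok = (
                    0 < gp < L - 1
                    and c > 0
                    and c + 1 < ncol
                    and ga[c - 1] != GAP
                    and ra[c - 1] != GAP
                    and ga[c + 1] != GAP
                    and ra[c + 1] != GAP
                )
                interior.append(ok)
            lut = np.zeros(128, dtype=np.int8)
            for base, i in zip(BASES, range(4)):
                lut[ord(base)] = i
            self._arrays = (
                lut[np.asarray(g_idx, dtype=np.uint8)],
                lut[np.asarray(y_idx, dtype=np.uint8)],
                np.asarray(g_pos, dtype=np.int64),
                np.asarray(interior, dtype=bool),
            )
        return self._arrays


def needleman_wunsch(
    genotype: str,
    read: str,
    scores: np.ndarray,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    homopolymer_gap_penalty: float = DEFAULT_HOMOPOLYMER_GAP_PENALTY,
) -> PairwiseAlignment:
    """Optimal global alignment under per-column scoring.

    Column scores come from ``scores`` (4x4, typically ``5 + ln T``); each gap
    column is charged ``gap_penalty`` except homopolymer gap columns which are
    charged ``homopolymer_gap_penalty``.  Terminal gaps are treated like
    internal ones.  Traceback ties prefer diagonal, then a gap in the read,
    then a gap in the genotype, making the result deterministic.
    """
    if not genotype or not read:
        raise ValueError("needleman_wunsch: empty input sequence")
    g = encode(genotype)
    y = encode(read)
    score, P = _nw_fill(g, y, np.asarray(scores, dtype=np.float64),
                        float(gap_penalty), float(homopolymer_gap_penalty))
    # traceback
    i, j = len(genotype), len(read)
    ga, ra = [], []
    subs = []
    n_gap = 0
    while i > 0 or j > 0:
        code = P[i, j]
        if code == _DIAG:
            a, b = genotype[i - 1], read[j - 1]
            ga.append(a)
            ra.append(b)
            if a != b:
                subs.append((i - 1, a, b))
            i -= 1
            j -= 1
        elif code == _UP:
            ga.append(genotype[i - 1])
            ra.append(GAP)
            n_gap += 1
            i -= 1
        else:
            ga.append(GAP)
            ra.append(read[j - 1])
            n_gap += 1
            j -= 1
    subs.reverse()
    return PairwiseAlignment(
        genotype_aligned="".join(reversed(ga)),
        read_aligned="".join(reversed(ra)),
        score=float(score),
        substitutions=subs,
        n_gap_columns=n_gap,
    )


# ---------------------------------------------------------------------------
# Substitution signatures and indel families
# ---------------------------------------------------------------------------


def extract_signature(alignment: PairwiseAlignment) -> Tuple[tuple, ...]:
    """Canonical substitution signature: ordered (genotype position, from, to).

    Positions are 0-based on the ungapped genotype; gap columns are ignored,
    so sequences differing only by indel placement share a signature.  The
    empty tuple is the error-free signature.
    """
    return tuple(alignment.substitutions)


def apply_signature(genotype: str, signature: Tuple[tuple, ...]) -> str:
    """The genotype-with-substitutions string a signature represents."""
    chars = list(genotype)
    for pos, frm, to in signature:
        if chars[pos] != frm:
            raise ValueError(f"signature inconsistent with genotype at {pos}")
        chars[pos] = to
    return "".join(chars)


def signature_log_lambda(genotype: str, signature: Tuple[tuple, ...], T) -> float:
    """log lambda of a signature's canonical sequence against the genotype.

    Equals lambda_0 times the product of off/diagonal rate ratios at the
    substituted positions; with context-dependent rates the flanking bases
    are the genotype's own neighbors (termini fall back to the
    context-independent rates).
    """
    from .error_model import BASE_INDEX, ContextTransitionMatrix

    comp = BaseComposition.from_sequence(genotype)
    if isinstance(T, TransitionMatrix):
        log_lam = log_no_error_probability(comp, T)
        for pos, frm, to in signature:
            i, j = BASE_INDEX[frm], BASE_INDEX[to]
            log_lam += T.log_probs[i, j] - T.log_probs[i, i]
        return log_lam
    if isinstance(T, ContextTransitionMatrix):
        L = len(genotype)
        log_lam = 0.0
        sig_pos = {pos: (frm, to) for pos, frm, to in signature}
        for p, base in enumerate(genotype):
            i = BASE_INDEX[base]
            j = BASE_INDEX[sig_pos[p][1]] if p in sig_pos else i
            if p == 0 or p == L - 1:
                log_lam += T.fallback.log_probs[i, j]
            else:
                log_lam += T.matrices[(genotype[p - 1], genotype[p + 1])].log_probs[i, j]
        return log_lam
    raise TypeError(f"unsupported matrix type: {type(T)!r}")


@dataclass
class IndelFamily:
    """Reads in a cluster sharing one substitution signature vs. the genotype.

    ``sequence`` is the genotype with the signature's substitutions applied
    (indels ignored); ``reads`` is the summed abundance r_y of the member
    unique sequences; ``log_lambda`` is the per-read probability of the
    error combination under the current T.
    """

    signature: Tuple[tuple, ...]
    members: list
    sequence: str
    reads: int
    log_lambda: float
    p_value: float | None = None

    @property
    def lam(self) -> float:
        return float(np.exp(self.log_lambda))


def build_indel_families(members, genotype: str, T, scores: np.ndarray,
                         aligner=None) -> list[IndelFamily]:
    """Group a cluster's unique sequences into indel families.

    Each member is aligned to the genotype, its substitution signature
    extracted, and reads of sequences sharing a signature are summed.  All
    members of a family share the family's lambda.  Families are ordered by
    descending read count, then ascending lambda, then signature.

    ``aligner(sequence, genotype)`` may be supplied to reuse cached
    alignments; it defaults to a fresh Needleman-Wunsch per member.
    """
    if not members:
        raise ValueError("build_indel_families: empty member list")
    if aligner is None:
        aligner = lambda seq, gen: needleman_wunsch(gen, seq, scores)
    groups: dict[tuple, list] = {}
    for m in members:
        if m.sequence == genotype:
            sig = ()
        else:
            sig = extract_signature(aligner(m.sequence, genotype))
        groups.setdefault(sig, []).append(m)
    families = []
    for sig, mem in groups.items():
        mem = sorted(mem, key=lambda u: (-u.abundance, u.sequence))
        families.append(
            IndelFamily(
                signature=sig,
                members=mem,
                sequence=apply_signature(genotype, sig),
                reads=sum(u.abundance for u in mem),
                log_lambda=signature_log_lambda(genotype, sig, T),
            )
        )
    families.sort(key=lambda f: (-f.reads, f.log_lambda, f.signature))
    return families
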