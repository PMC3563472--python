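"""Divisive model-based clustering with alternating error-rate re-estimation.

Each precluster starts as a single cluster containing all its sequences.  The
middle loop repeatedly (a) runs an inner k-means-like alternation -- update
each cluster's genotype, then reassign every sequence to the cluster
maximizing the expected number of reads of that sequence, rho * lambda --
until nothing moves, then (b) tests the partition against the error model
with Bonferroni-corrected abundance and read p-values, splitting off the most
statistically inconsistent family as a new cluster when a test fails.
Families significant under the abundance p-value take priority for seeding.

The outer loop alternates this clustering (over all preclusters) with a
pooled maximum-likelihood re-estimation of the substitution rates T, until T
converges (max-abs change below tolerance), revisits a previous value, or a
round cap is hit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import (
    PairwiseAlignment,
    build_indel_families,
    needleman_wunsch,
    score_matrix_from_T,
    signature_log_lambda,
)
from .error_model import (
    BaseComposition,
    ContextTransitionMatrix,
    TransitionMatrix,
    encode,
    estimate_T_context_mle,
    log_genotype_error_probability,
    tally_substitutions,
    error_rates_payload,
)
from .precluster import single_linkage_preclusters
from .pvalues import abundance_pvalue, read_pvalue
from .seqio import ReadSet, UniqueSequence

logger = logging.getLogger(__name__)

DEFAULT_OMEGA_A = 1e-40
DEFAULT_OMEGA_R = 1e-3
DEFAULT_TOL = 1e-9
DEFAULT_MAX_ROUNDS = 10
INNER_SWEEP_CAP = 100


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    """A conjectured genotype and the sequences hypothesized to be its errors."""

    genotype: str
    members: list[UniqueSequence]
    families: list = field(default_factory=list)
    q_value: float | None = None

    @property
    def rho(self) -> int:
        return sum(m.abundance for m in self.members)

    @property
    def log_lambda_star(self) -> float:
        return min(f.log_lambda for f in self.families)


@dataclass
class Partition:
    """The clusters of one precluster."""

    clusters: list[Cluster]
    precluster_id: int = 0

    @property
    def total_reads(self) -> int:
        return sum(c.rho for c in self.clusters)

    @property
    def n_families(self) -> int:
        return sum(len(c.families) for c in self.clusters)

    def aligned_pairs(self, aligner):
        """(alignment, read weight) for every member against its cluster genotype."""
        for c in self.clusters:
            for m in c.members:
                yield aligner(m.sequence, c.genotype), m.abundance


@dataclass
class DadaResult:
    """Output of :func:`dada`: genotypes, error rates and diagnostics."""

    genotypes: list[tuple[str, int]]
    partitions: list[Partition]
    T: TransitionMatrix
    T_context: ContextTransitionMatrix | None
    counts: np.ndarray  # pooled pre-floor substitution counts N_ij at the last round
    trace: list[dict]
    status: str  # converged | cycled | max_rounds
    n_rounds: int
    total_reads: int

    def genotype_index(self) -> dict[str, int]:
        return {seq: i for i, (seq, _n) in enumerate(self.genotypes)}

    def assignment(self) -> dict[str, int]:
        """Map each unique read sequence to its inferred genotype's index."""
        gidx = self.genotype_index()
        out = {}
        for part in self.partitions:
            for c in part.clusters:
                gi = gidx[c.genotype]
                for m in c.members:
                    out[m.sequence] = gi
        return out

    def membership_table(self) -> pd.DataFrame:
        rows = []
        gidx = self.genotype_index()
        for part in self.partitions:
            for c in part.clusters:
                fam_of = {}
                for f in c.families:
                    for m in f.members:
                        fam_of[m.sequence] = f
                for m in c.members:
                    f = fam_of[m.sequence]
                    rows.append(
                        {
                            "read_id": m.id,
                            "sequence": m.sequence,
                            "abundance": m.abundance,
                            "cluster_id": gidx[c.genotype],
                            "family_signature": ";".join(
                                f"{p}{a}>{b}" for p, a, b in f.signature
                            ),
                            "lambda": f.lam,
                            "p_value": f.p_value,
                        }
                    )
        return pd.DataFrame(rows)

    def error_rates(self) -> dict:
        return error_rates_payload(self.T, self.T_context)


# ---------------------------------------------------------------------------
# Cached alignment
# ---------------------------------------------------------------------------


def make_cached_aligner(scores: np.ndarray):
    """Aligner ``(sequence, genotype) -> PairwiseAlignment`` with memoization.

    Valid only while the score matrix (hence T) is fixed; build a fresh one
    each outer round.
    """
    cache: dict[tuple[str, str], PairwiseAlignment] = {}
    diag = np.diag(np.asarray(scores))

    def aligner(seq: str, genotype: str) -> PairwiseAlignment:
        key = (seq, genotype)
        aln = cache.get(key)
        if aln is None:
            if seq == genotype:
                aln = PairwiseAlignment(
                    genotype_aligned=genotype,
                    read_aligned=seq,
                    score=float(diag[encode(genotype)].sum()),
                    substitutions=[],
                    n_gap_columns=0,
                )
            else:
                aln = needleman_wunsch(genotype, seq, scores)
            cache[key] = aln
        return aln

    aligner.log_lambda_cache = {}
    return aligner


# ---------------------------------------------------------------------------
# Algorithm steps
# ---------------------------------------------------------------------------


def _modal_sequence(members: list[UniqueSequence]) -> str:
    """Most abundant member sequence; ties break lexicographically."""
    return min(members, key=lambda m: (-m.abundance, m.sequence)).sequence


def _rebuild_families(cluster: Cluster, T, scores, aligner) -> None:
    cluster.families = build_indel_families(
        cluster.members, cluster.genotype, T, scores, aligner=aligner
    )


def initial_partition(members, T, scores, aligner=None, precluster_id: int = 0) -> Partition:
    """The trivial partition: one cluster holding every sequence.

    The genotype is the modal (most abundant, ties lexicographic) sequence.
    """
    if not members:
        raise ValueError("initial_partition: empty member list")
    if aligner is None:
        aligner = make_cached_aligner(scores)
    cluster = Cluster(genotype=_modal_sequence(members), members=list(members))
    _rebuild_families(cluster, T, scores, aligner)
    return Partition(clusters=[cluster], precluster_id=precluster_id)


def update_genotypes(partition: Partition, T, scores, aligner) -> tuple[Partition, int]:
    """Set each cluster's genotype to its current consensus (modal) sequence.

    The consensus is the most-abundant indel family's most-abundant member.
    Families are rebuilt against any changed genotype.  Returns the partition
    and the number of genotypes that changed.
    """
    n_changed = 0
    for c in partition.clusters:
        if not c.families:
            _rebuild_families(c, T, scores, aligner)
        top_family = c.families[0]  # sorted by descending reads
        candidate = top_family.members[0].sequence
        if candidate != c.genotype:
            c.genotype = candidate
            _rebuild_families(c, T, scores, aligner)
            n_changed += 1
    return partition, n_changed


def reassign_sweep(partition: Partition, T, scores, aligner) -> tuple[Partition, int]:
    """One synchronous reassignment sweep: each sequence joins argmax rho * lambda.

    All assignments are computed against the rho values held fixed from the
    sweep's start, then applied together.  Ties go to the cluster with larger
    rho, then lower index.  Clusters emptied by the moves are deleted.
    """
    clusters = partition.clusters
    if len(clusters) <= 1:
        return partition, 0
    rho0 = [c.rho for c in clusters]
    log_rho0 = [np.log(r) for r in rho0]
    ll_cache = getattr(aligner, "log_lambda_cache", {})
    moves: list[tuple[UniqueSequence, int, int]] = []
    for ci, c in enumerate(clusters):
        for m in c.members:
            best = None
            for ai, a in enumerate(clusters):
                key = (m.sequence, a.genotype)
                ll = ll_cache.get(key)
                if ll is None:
                    ll = log_genotype_error_probability(aligner(*key), T)
                    ll_cache[key] = ll
                score = log_rho0[ai] + ll
                key = (score, rho0[ai], -ai)
                if best is None or key > best[0]:
                    best = (key, ai)
            if best[1] != ci:
                moves.append((m, ci, best[1]))
    for m, src, dst in moves:
        clusters[src].members.remove(m)
        clusters[dst].members.append(m)
    emptied = [c for c in clusters if not c.members]
    for c in emptied:
        logger.debug("cluster with genotype %.20s... emptied and deleted", c.genotype)
        clusters.remove(c)
    if moves:
        for c in clusters:
            c.members.sort(key=lambda m: (-m.abundance, m.sequence))
            _rebuild_families(c, T, scores, aligner)
    return partition, len(moves)


def _partition_state(partition: Partition) -> tuple:
    return tuple(
        sorted((c.genotype, tuple(sorted(m.id for m in c.members))) for c in partition.clusters)
    )


def _inner_fixed_point(partition: Partition, T, scores, aligner) -> None:
    """Alternate genotype updates and reassignment sweeps to a fixed point.

    Synchronous sweeps can enter short cycles (rho changes flip near-tied
    assignments back and forth); a revisited partition state terminates the
    loop deterministically, with the sweep cap as backstop.
    """
    seen = {_partition_state(partition)}
    for _ in range(INNER_SWEEP_CAP):
        _, n_geno = update_genotypes(partition, T, scores, aligner)
        _, n_moves = reassign_sweep(partition, T, scores, aligner)
        if n_geno == 0 and n_moves == 0:
            return
        state = _partition_state(partition)
        if state in seen:
            return
        seen.add(state)
    warnings.warn("inner reassignment loop hit its sweep cap", RuntimeWarning)


def compute_statistics(
    partition: Partition,
    T_q: TransitionMatrix,
    omega_r: float,
    T_assign=None,
) -> None:
    """Fill per-family abundance p-values and per-cluster read p-values.

    The read p-value is always computed with the context-independent matrix
    ``T_q``; lambda* is likewise evaluated context-independently so that the
    threshold is commensurate with the gamma-sum terms.
    """
    n_clusters = len(partition.clusters)
    for c in partition.clusters:
        rho = c.rho
        for f in c.families:
            lam = min(max(f.lam, 5e-324), 1.0 - 1e-16)
            f.p_value = abundance_pvalue(f.reads, lam, rho)
        log_lstar = min(
            signature_log_lambda(c.genotype, f.signature, T_q) for f in c.families
        )
        comp = BaseComposition.from_sequence(c.genotype)
        c.q_value = read_pvalue(
            float(np.exp(log_lstar)),
            rho,
            comp,
            T_q,
            stop_below=omega_r / n_clusters,
        )


def split_cluster(
    partition: Partition,
    T,
    scores,
    aligner,
    omega_a: float,
    omega_r: float,
) -> tuple[Partition, bool]:
    """Seed a new cluster with the most statistically inconsistent family.

    Requires p-values to be current (:func:`compute_statistics`).  Families
    failing the Bonferroni abundance test take priority; otherwise a cluster
    failing the read test donates the family attaining lambda*.  Only the
    seeding family's reads move; everything else relocates in later sweeps.
    The error-free family (sequence identical to the genotype) never seeds.
    """
    n_f = partition.n_families
    n_b = len(partition.clusters)

    candidates = []  # (p, -reads, sequence, cluster index, family)
    for ci, c in enumerate(partition.clusters):
        for f in c.families:
            if f.sequence == c.genotype:
                continue
            candidates.append((f.p_value, -f.reads, f.sequence, ci, f))
    seed = None
    if candidates:
        best = min(candidates)
        if best[0] < omega_a / n_f:
            seed = (best[3], best[4])
    if seed is None:
        read_failures = [
            (c.q_value, -c.rho, ci)
            for ci, c in enumerate(partition.clusters)
            if c.q_value is not None and c.q_value < omega_r / n_b
        ]
        if read_failures:
            _, _, ci = min(read_failures)
            c = partition.clusters[ci]
            fams = [
                (f.log_lambda, -f.reads, f.sequence, f)
                for f in c.families
                if f.sequence != c.genotype
            ]
            if fams:
                seed = (ci, min(fams)[3])
    if seed is None:
        return partition, False

    ci, family = seed
    src = partition.clusters[ci]
    for m in family.members:
        src.members.remove(m)
    new = Cluster(genotype=family.sequence, members=list(family.members))
    if src.members:
        _rebuild_families(src, T, scores, aligner)
    else:
        partition.clusters.remove(src)
    new.members.sort(key=lambda m: (-m.abundance, m.sequence))
    _rebuild_families(new, T, scores, aligner)
    partition.clusters.append(new)
    return partition, True


def cluster_precluster(
    members,
    T,
    omega_a: float,
    omega_r: float,
    scores=None,
    T_q: TransitionMatrix | None = None,
    aligner=None,
    precluster_id: int = 0,
) -> Partition:
    """Divisively cluster one precluster under a fixed error model.

    Alternates inner fixed-point sweeps with splits until the Bonferroni
    abundance and read tests both pass (or no seedable family remains; the
    middle loop is capped at the number of unique sequences).
    """
    if T_q is None:
        if not isinstance(T, TransitionMatrix):
            raise ValueError("T_q required when clustering with context-dependent T")
        T_q = T
    if scores is None:
        scores = score_matrix_from_T(T_q)
    if aligner is None:
        aligner = make_cached_aligner(scores)
    partition = initial_partition(members, T, scores, aligner, precluster_id)
    _inner_fixed_point(partition, T, scores, aligner)
    for _ in range(len(members)):
        compute_statistics(partition, T_q, omega_r, T_assign=T)
        abund_ok = all(
            f.p_value >= omega_a / partition.n_families
            for c in partition.clusters
            for f in c.families
            if f.sequence != c.genotype
        )
        read_ok = all(
            c.q_value >= omega_r / len(partition.clusters) for c in partition.clusters
        )
        if abund_ok and read_ok:
            break
        _, did_split = split_cluster(partition, T, scores, aligner, omega_a, omega_r)
        if not did_split:
            break
        _inner_fixed_point(partition, T, scores, aligner)
    else:  # pragma: no cover - cap equals the number of unique sequences
        warnings.warn("middle loop hit the split cap", RuntimeWarning)
    compute_statistics(partition, T_q, omega_r, T_assign=T)
    return partition


# ---------------------------------------------------------------------------
# Outer loop
# ---------------------------------------------------------------------------


def _round_significant(x: np.ndarray, digits: int = 12) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        mag = np.where(x == 0, 0, np.floor(np.log10(np.abs(x, where=x != 0, out=np.ones_like(x)))))
    factor = 10.0 ** (digits - 1 - mag)
    return np.round(x * factor) / factor


def _model_hash(T: TransitionMatrix, T_ctx: ContextTransitionMatrix | None) -> bytes:
    parts = [_round_significant(T.probs).tobytes()]
    if T_ctx is not None:
        for key in sorted(T_ctx.matrices):
            parts.append(_round_significant(T_ctx.matrices[key].probs).tobytes())
    return b"".join(parts)


def dada(
    readset: ReadSet,
    omega_a: float = DEFAULT_OMEGA_A,
    omega_r: float = DEFAULT_OMEGA_R,
    precluster_cutoff: float = 0.03,
    context: bool = False,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
    tol: float = DEFAULT_TOL,
) -> DadaResult:
    """Run the full denoising algorithm on a dereplicated read set.

    Preclusters are computed once; the initial T is the pooled MLE under each
    precluster's trivial partition; clustering and pooled re-estimation then
    alternate until T converges (see module docstring).  Returns the inferred
    genotypes with read abundances, the final error model and diagnostics.
    """
    if len(readset) == 0:
        raise ValueError("dada: empty input")
    preclusters = single_linkage_preclusters(readset, cutoff=precluster_cutoff)

    # T0: pooled MLE under the trivial partitions
    scores0 = score_matrix_from_T(TransitionMatrix.uniform(1e-3))
    aligner0 = make_cached_aligner(scores0)
    counts = np.zeros((4, 4))
    for pc in preclusters:
        genotype = _modal_sequence(pc.members)
        counts += tally_substitutions(
            (aligner0(m.sequence, genotype), m.abundance) for m in pc.members
        )
    T = TransitionMatrix.from_counts(counts, warn=False)
    T_ctx = None
    if context:
        pairs0 = []
        for pc in preclusters:
            genotype = _modal_sequence(pc.members)
            pairs0.extend((aligner0(m.sequence, genotype), m.abundance) for m in pc.members)
        T_ctx = estimate_T_context_mle(pairs0, warn=False)

    trace: list[dict] = []
    status = "max_rounds"
    seen = {_model_hash(T, T_ctx)}
    partitions: list[Partition] = []
    n_rounds = 0
    for round_idx in range(1, max_rounds + 1):
        n_rounds = round_idx
        scores = score_matrix_from_T(T)
        aligner = make_cached_aligner(scores)
        T_assign = T_ctx if context else T
        partitions = [
            cluster_precluster(
                pc.members,
                T_assign,
                omega_a,
                omega_r,
                scores=scores,
                T_q=T,
                aligner=aligner,
                precluster_id=pc.id,
            )
            for pc in preclusters
        ]
        pairs = [
            pair for part in partitions for pair in part.aligned_pairs(aligner)
        ]
        counts = tally_substitutions(pairs)
        T_new = TransitionMatrix.from_counts(counts, warn=False)
        T_ctx_new = estimate_T_context_mle(pairs, warn=False) if context else None
        diff = T.max_abs_difference(T_new)
        if context:
            diff = max(
                diff,
                max(
                    T_ctx.matrices[k].max_abs_difference(T_ctx_new.matrices[k])
                    for k in T_ctx.matrices
                ),
            )
        trace.append(
            {
                "round": round_idx,
                "T_distance": diff,
                "n_clusters": sum(len(p.clusters) for p in partitions),
                "min_p": min(
                    (
                        f.p_value
                        for p in partitions
                        for c in p.clusters
                        for f in c.families
                        if f.p_value is not None
                    ),
                    default=None,
                ),
                "min_q": min(
                    (c.q_value for p in partitions for c in p.clusters), default=None
                ),
            }
        )
        T, T_ctx = T_new, T_ctx_new
        if diff < tol:
            status = "converged"
            break
        h = _model_hash(T, T_ctx)
        if h in seen:
            status = "cycled"
            break
        seen.add(h)
    if status == "max_rounds":
        warnings.warn(
            f"error model did not converge within {max_rounds} rounds", RuntimeWarning
        )

    genotype_counts: dict[str, int] = {}
    for part in partitions:
        for c in part.clusters:
            genotype_counts[c.genotype] = genotype_counts.get(c.genotype, 0) + c.rho
    genotypes = sorted(genotype_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return DadaResult(
        genotypes=genotypes,
        partitions=partitions,
        T=T,
        T_context=T_ctx,
        counts=counts,
        trace=trace,
        status=status,
        n_rounds=n_rounds,
        total_reads=readset.total_reads,
    )
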