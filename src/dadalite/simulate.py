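"""Synthetic amplicon communities with the error model's statistical structure.

Stands in for 454 control data sets (mixtures of known clones amplified
together): known genotypes, per-site multinomial substitutions drawn from a
true transition matrix, optional indels (enriched inside homopolymer runs,
as on 454), and abundances spanning orders of magnitude -- with full
ground-truth bookkeeping so that every inference stage can be tested.

Substitutions are applied first (recording the true substitution signature in
genotype coordinates), then indels; the inference models only substitutions,
so simulated indels exercise the indel-family machinery exactly as real 454
data did.  An optional two-stage scheme (error-bearing template molecules
resampled into reads) mimics early-round PCR lineage effects, i.e. the
overdispersion real data shows relative to the independence assumption; it is
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import needleman_wunsch, score_matrix_from_T
from .error_model import (
    BASES,
    BaseComposition,
    ContextTransitionMatrix,
    TransitionMatrix,
    encode,
    log_no_error_probability,
    log_genotype_error_probability,
    BASE_INDEX,
)
from .pvalues import abundance_pvalue, read_pvalue
from .seqio import ReadSet, dereplicate

# default per-pair off-diagonal rates: complement-symmetric, spanning the
# range typical of PCR+454 substitution errors
DEFAULT_RATE_RANGE = (2e-4, 2e-3)
DEFAULT_INDEL_RATE = 5e-4
DEFAULT_HOMOPOLYMER_MULTIPLIER = 4.0


def complement_symmetric_T(rates=None) -> TransitionMatrix:
    """A transition matrix whose complementary error rates are exactly equal.

    ``rates`` gives the six free off-diagonal probabilities for the error
    pairs (A>G/T>C, C>T/G>A, A>T/T>A, C>A/G>T, A>C/T>G, C>G/G>C), defaulting
    to six log-spaced values in ``DEFAULT_RATE_RANGE``.
    """
    if rates is None:
        rates = np.geomspace(DEFAULT_RATE_RANGE[1], DEFAULT_RATE_RANGE[0], 6)
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (6,):
        raise ValueError("expected 6 pair rates")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    canonical = [("A", "G"), ("C", "T"), ("A", "T"), ("C", "A"), ("A", "C"), ("C", "G")]
    probs = np.zeros((4, 4))
    for (i, j), r in zip(canonical, rates):
        probs[BASE_INDEX[i], BASE_INDEX[j]] = r
        probs[BASE_INDEX[comp[i]], BASE_INDEX[comp[j]]] = r
    for i in range(4):
        probs[i, i] = 1.0 - probs[i].sum()
    return TransitionMatrix(probs)


def random_genotypes(
    n: int, length: int, min_dist: int, rng: np.random.Generator
) -> list[str]:
    """Random ACGT genotypes with pairwise Hamming distance >= min_dist."""
    out: list[np.ndarray] = []
    attempts = 0
    while len(out) < n:
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != g).sum()) >= min_dist for g in out):
            out.append(cand)
        attempts += 1
        if attempts > 100 * n:
            raise RuntimeError("could not place genotypes at the requested distance")
    return ["".join(BASES[i] for i in g) for g in out]


@dataclass(frozen=True)
class CommunitySpec:
    """The stated world a simulation draws from."""

    genotypes: tuple[str, ...]
    abundances: tuple[int, ...]
    T_true: TransitionMatrix | ContextTransitionMatrix = field(
        default_factory=complement_symmetric_T
    )
    indel_rate: float = DEFAULT_INDEL_RATE
    homopolymer_indel_multiplier: float = DEFAULT_HOMOPOLYMER_MULTIPLIER
    seed: int = 0
    pcr_templates: int | None = None  # two-stage lineage scheme; None = off

    def __post_init__(self):
        if len(self.genotypes) != len(self.abundances):
            raise ValueError("genotypes and abundances must align")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("genotypes must be pairwise distinct")
        if any(a < 1 for a in self.abundances):
            raise ValueError("abundances must be >= 1")
        if not (0.0 <= self.indel_rate <= 0.05):
            raise ValueError("indel_rate must lie in [0, 0.05]")
        if self.homopolymer_indel_multiplier < 1:
            raise ValueError("homopolymer multiplier must be >= 1")


@dataclass(frozen=True)
class SimulatedRead:
    """Ground truth for one emitted read."""

    genotype_index: int
    signature: tuple  # (position, from_base, to_base) on the genotype
    indels: tuple  # (genotype position, 'ins'|'del', base)
    sequence: str


@dataclass
class GroundTruth:
    """Per-read provenance for a simulated data set."""

    spec: CommunitySpec
    reads: list[SimulatedRead]

    def substitution_counts(self) -> np.ndarray:
        """True N_ij tallies (before indels), read-weighted."""
        counts = np.zeros((4, 4))
        for rec in self.reads:
            gi = encode(self.spec.genotypes[rec.genotype_index])
            np.add.at(counts, (gi, gi), 1.0)
            for pos, frm, to in rec.signature:
                i, j = BASE_INDEX[frm], BASE_INDEX[to]
                counts[i, i] -= 1.0
                counts[i, j] += 1.0
        return counts

    def opportunities(self) -> np.ndarray:
        """N_i: read-weighted genotype base counts (binomial trial counts)."""
        n = np.zeros(4)
        for g, a in zip(self.spec.genotypes, self.spec.abundances):
            comp = BaseComposition.from_sequence(g)
            n += a * np.asarray(comp.counts, dtype=float)
        return n


def _row_probs(spec: CommunitySpec, genotype: str) -> np.ndarray:
    """Per-site substitution probability rows, shape (L, 4)."""
    gi = encode(genotype)
    T = spec.T_true
    if isinstance(T, TransitionMatrix):
        return T.probs[gi]
    L = len(genotype)
    rows = np.empty((L, 4))
    for p in range(L):
        if p == 0 or p == L - 1:
            rows[p] = T.fallback.probs[gi[p]]
        else:
            rows[p] = T.matrices[(genotype[p - 1], genotype[p + 1])].probs[gi[p]]
    return rows


def simulate_reads(spec: CommunitySpec) -> tuple[ReadSet, GroundTruth]:
    """Draw reads i.i.d. per genotype under the substitution + indel model.

    Each site of each read substitutes independently according to the true
    transition matrix; indels are then inserted/deleted per site at
    ``indel_rate``, multiplied inside homopolymer runs.  Seeded and fully
    reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    truth_reads: list[SimulatedRead] = []
    raw: list[str] = []
    for k, (genotype, abundance) in enumerate(zip(spec.genotypes, spec.abundances)):
        gi = encode(genotype)
        L = len(genotype)
        rows = _row_probs(spec, genotype)
        cum = np.cumsum(rows, axis=1)
        cum[:, -1] = 1.0

        if spec.pcr_templates:
            # two-stage: draw M template molecules with errors, resample reads
            n_templates = spec.pcr_templates
            t_draw = rng.random((n_templates, L))
            t_bases = (t_draw[:, :, None] > cum[None, :, :]).sum(axis=2)
            choice = rng.integers(0, n_templates, size=abundance)
            bases = t_bases[choice]
        else:
            draw = rng.random((abundance, L))
            bases = (draw[:, :, None] > cum[None, :, :]).sum(axis=2)

        indel_p = np.full(L, spec.indel_rate)
        if spec.indel_rate > 0:
            run = np.zeros(L, dtype=bool)
            run[1:] = gi[1:] == gi[:-1]
            indel_p[run] *= spec.homopolymer_indel_multiplier
            indel_mask = rng.random((abundance, L)) < indel_p[None, :]
        else:
            indel_mask = np.zeros((abundance, L), dtype=bool)

        for r in range(abundance):
            b = bases[r]
            sig = tuple(
                (int(p), BASES[gi[p]], BASES[b[p]])
                for p in np.nonzero(b != gi)[0]
            )
            indels = []
            if indel_mask[r].any():
                chars = [BASES[i] for i in b]
                # apply right-to-left so genotype positions stay valid
                for p in np.nonzero(indel_mask[r])[0][::-1]:
                    if rng.random() < 0.5:
                        del chars[p]
                        indels.append((int(p), "del", BASES[gi[p]]))
                    else:
                        ins = BASES[rng.integers(0, 4)]
                        chars.insert(p, ins)
                        indels.append((int(p), "ins", ins))
                seq = "".join(chars)
                indels.reverse()
            else:
                seq = "".join(BASES[i] for i in b)
            if not seq:
                seq = BASES[rng.integers(0, 4)]  # degenerate: everything deleted
            raw.append(seq)
            truth_reads.append(
                SimulatedRead(
                    genotype_index=k,
                    signature=sig,
                    indels=tuple(indels),
                    sequence=seq,
                )
            )
    return dereplicate(raw), GroundTruth(spec=spec, reads=truth_reads)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def discrimination_data(
    partition,
    T: TransitionMatrix,
    omega_a: float = 0.01,
    omega_r: float = 1e-3,
    n_grid: int = 60,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family (abundance, effective distance) points plus decision boundaries.

    The effective distance is ``ln(lambda / lambda_0) / ln(T_AG / T_AA)`` --
    log lambda scaled by the most common error probability so that one
    A->G substitution sits at distance 1 and the error-free family at 0.

    The boundary frame holds, per lambda grid point, the largest abundance
    still accepted by the Bonferroni abundance test, and carries the read
    p-value lambda cutoff as an attribute column ``lambda_star_cutoff``.
    """
    scale = float(T.log_probs[0, 2] - T.log_probs[0, 0])  # ln(T_AG / T_AA)
    rows = []
    n_f = sum(len(c.families) for c in partition.clusters)
    for ci, c in enumerate(partition.clusters):
        comp = BaseComposition.from_sequence(c.genotype)
        log_lam0 = log_no_error_probability(comp, T)
        for f in c.families:
            rows.append(
                {
                    "cluster_id": ci,
                    "reads": f.reads,
                    "lambda": f.lam,
                    "log_lambda": f.log_lambda,
                    "effective_distance": (f.log_lambda - log_lam0) / scale,
                    "p_value": f.p_value,
                }
            )
    fam_df = pd.DataFrame(rows)

    # abundance acceptance boundary for the largest cluster
    main = max(partition.clusters, key=lambda c: c.rho)
    comp = BaseComposition.from_sequence(main.genotype)
    log_lam0 = log_no_error_probability(comp, T)
    rho = main.rho
    bound_rows = []
    max_dist = max(5.0, fam_df["effective_distance"].max() + 1 if len(fam_df) else 5.0)
    threshold = omega_a / max(n_f, 1)
    for d in np.linspace(0.0, max_dist, n_grid):
        lam = float(np.exp(log_lam0 + d * scale))
        lam = min(max(lam, 5e-324), 1 - 1e-16)
        lo, hi = 1, rho
        # largest r with p_y >= threshold (p_y is non-increasing in r)
        if abundance_pvalue(1, lam, rho) < threshold:
            r_max = 0
        else:
            while lo < hi:
                mid = (lo + hi + 1) // 2
                if abundance_pvalue(mid, lam, rho) >= threshold:
                    lo = mid
                else:
                    hi = mid - 1
            r_max = lo
        bound_rows.append({"effective_distance": d, "lambda": lam, "max_reads": r_max})
    boundary = pd.DataFrame(bound_rows)
    boundary.attrs["lambda_star_cutoff"] = _read_pvalue_cutoff(
        comp, rho, T, omega_r / max(len(partition.clusters), 1)
    )
    return fam_df, boundary


def _read_pvalue_cutoff(comp, rho, T, threshold, n_iter: int = 40) -> float:
    """Largest lambda* whose read p-value is still below ``threshold`` (bisection)."""
    log_lam0 = log_no_error_probability(comp, T)
    lo, hi = log_lam0 - 80.0, log_lam0  # q(lambda*) is nondecreasing in lambda*
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        q = read_pvalue(float(np.exp(mid)), rho, comp, T, stop_below=threshold)
        if q < threshold:
            lo = mid
        else:
            hi = mid
    return float(np.exp(lo))


def rejoin_thresholds(result) -> list[float]:
    """Omega_a values at which each non-largest cluster rejoins another cluster.

    For each cluster (all but the largest), the abundance p-value its seed
    (error-free) family would obtain as a member of the best alternative
    cluster -- argmax over other clusters of rho * lambda -- is multiplied by
    the Bonferroni family count.  Histograms of these values show where the
    abundance threshold could be lowered before clusters merge; the first
    large gap separates genuine genotypes from model departures.
    """
    clusters = [c for part in result.partitions for c in part.clusters]
    if len(clusters) < 2:
        return []
    n_f = sum(len(c.families) for c in clusters)
    scores = score_matrix_from_T(result.T)
    largest = max(range(len(clusters)), key=lambda i: (clusters[i].rho, -i))
    out = []
    for ci, c in enumerate(clusters):
        if ci == largest:
            continue
        best = None
        for ai, alt in enumerate(clusters):
            if ai == ci:
                continue
            aln = needleman_wunsch(alt.genotype, c.genotype, scores)
            ll = log_genotype_error_probability(aln, result.T)
            key = (np.log(alt.rho) + ll, alt.rho, -ai)
            if best is None or key > best[0]:
                best = (key, ai, ll)
        _, ai, ll = best
        alt = clusters[ai]
        seed_reads = next(
            (f.reads for f in c.families if f.sequence == c.genotype), c.rho
        )
        lam = min(max(float(np.exp(ll)), 5e-324), 1 - 1e-16)
        p = abundance_pvalue(seed_reads, lam, alt.rho + c.rho)
        out.append(p * n_f)
    return sorted(out)
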