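"""scikit-learn-style estimator facade for the denoiser.

The algorithm is clustering-shaped, so it is exposed as an estimator that
composes with sklearn tooling: ``fit`` takes a sequence of read strings (or a
:class:`~dadalite.seqio.ReadSet`), fitted attributes carry the inferred
genotypes, per-read labels and error rates, and ``get_params``/``set_params``
work as usual.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .clustering import (
    DEFAULT_MAX_ROUNDS,
    DEFAULT_OMEGA_A,
    DEFAULT_OMEGA_R,
    DEFAULT_TOL,
    dada,
)
from .seqio import ReadSet, dereplicate


class DadaDenoiser(ClusterMixin, BaseEstimator):
    """Infer sample genotypes and substitution-error rates from amplicon reads.

    Parameters
    ----------
    omega_a : float
        Joint significance threshold for the abundance p-value (how many
        identical reads are too many to be errors).  Very small values give
        conservative diversity estimates.
    omega_r : float
        Joint significance threshold for the read p-value (how far away a
        read may be and still be an error); governs singleton decisions.
    precluster_cutoff : float
        Single-linkage substitution-distance cutoff for the coarse
        preclustering (default 3%).
    context : bool
        Use nearest-neighbor context-dependent substitution rates when
        clustering (the read p-value stays context-independent).
    max_rounds : int
        Cap on outer clustering/re-estimation rounds.
    tol : float
        Convergence tolerance on the max-abs change of T between rounds.

    Attributes
    ----------
    result_ : DadaResult
        Full result object (partitions, trace, convergence status).
    genotypes_ : list of str
        Inferred genotype sequences, by descending read abundance.
    abundances_ : ndarray of int
        Reads assigned to each genotype.
    labels_ : ndarray of int
        Genotype index for each input read (in input order).
    error_rates_ : ndarray, shape (4, 4)
        Inferred substitution probabilities P(read j | sample i), ACGT order.
    n_iter_ : int
        Outer rounds executed.

    Examples
    --------
    >>> den = DadaDenoiser(omega_a=1e-40, omega_r=1e-3)
    >>> labels = den.fit_predict(["ACGTACGT", "ACGTACGT", "ACGAACGT"])
    """

    def __init__(
        self,
        omega_a: float = DEFAULT_OMEGA_A,
        omega_r: float = DEFAULT_OMEGA_R,
        precluster_cutoff: float = 0.03,
        context: bool = False,
        max_rounds: int = DEFAULT_MAX_ROUNDS,
        tol: float = DEFAULT_TOL,
    ):
        self.omega_a = omega_a
        self.omega_r = omega_r
        self.precluster_cutoff = precluster_cutoff
        self.context = context
        self.max_rounds = max_rounds
        self.tol = tol

    def fit(self, X, y=None):
        """Denoise the reads in X (list of ACGT strings, or a ReadSet)."""
        if isinstance(X, ReadSet):
            readset = X
            raw = None
        else:
            raw = [str(s).upper() for s in X]
            if len(raw) == 0:
                raise ValueError("empty read list")
            readset = dereplicate(raw)
        result = dada(
            readset,
            omega_a=self.omega_a,
            omega_r=self.omega_r,
            precluster_cutoff=self.precluster_cutoff,
            context=self.context,
            max_rounds=self.max_rounds,
            tol=self.tol,
        )
        self.result_ = result
        self.genotypes_ = [g for g, _n in result.genotypes]
        self.abundances_ = np.array([n for _g, n in result.genotypes], dtype=int)
        assignment = result.assignment()
        if raw is not None:
            self.labels_ = np.array([assignment[s] for s in raw], dtype=int)
        else:
            self.labels_ = np.array(
                [assignment[m.sequence] for m in readset.members], dtype=int
            )
        self.error_rates_ = result.T.probs.copy()
        self.n_iter_ = result.n_rounds
        return self

    def fit_predict(self, X, y=None):
        """Fit and return per-read genotype labels."""
        return self.fit(X).labels_
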