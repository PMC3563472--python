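# Methods

## The problem

PCR amplification followed by high-throughput sequencing of a marker locus
(e.g. a 16S rRNA hypervariable region) produces reads contaminated by
substitution and indel errors. Clustering reads into fixed-radius OTUs
confounds fine-scale biological diversity with the error cloud around each
true sequence. `dadalite` instead infers, without any training data, the set
of *sample genotypes* G = {G_a}, the number of reads deriving from each, and
the substitution-error probabilities that generated the data.

## Error model

Each read originates from one genotype. Substitution errors are independent
across reads and across sites, and per site a sample base *i* is read as *j*
with probability `T[i, j]`, a 4x4 row-stochastic transition matrix (12 free
rates). Optionally the rates may depend on the two flanking genotype bases
(16 contexts x 12 = 192 free rates); sequence termini and positions next to
alignment gaps always use the context-independent rates.

The probability that errors convert genotype G_a into a particular sequence
(the *genotype error probability*, lambda) is the product of per-site
transition probabilities over aligned non-gap columns. Indels are not
modelled: reads in a cluster that share the same substitution set against
the genotype (the *indel family*) are pooled, and all statistics operate on
family read counts. The package consequently cannot separate sequences that
differ only by indels -- a documented model limitation, not a bug.

Under these assumptions the read count of family *y* in a cluster with rho
reads is Binomial(rho, lambda_ya), which yields two tail statistics:

- **Abundance p-value** `p_y = P(R >= r_y | R >= 1)` - are there *too many
  identical reads* for this family to be errors? Conditioning on R >= 1
  avoids a hopeless multiple-testing correction over all 4^L unobserved
  sequences; the price is that singletons always get p = 1.
- **Read p-value** `q_a`: the probability that at least one of rho reads is
  at least as improbable as the least probable observed family
  (lambda* = min_y lambda_ya). This handles singletons. The tail over all
  possible error sequences is organised by 4x4 off-diagonal count matrices
  gamma; all sequences with error type gamma share
  `lambda = lambda_0 * prod (T_ij/T_ii)^gamma_ij` and are counted exactly by
  a product of multinomial coefficients.

Both are tested with Bonferroni corrections, `Omega_a / |F|` against all
families and `Omega_r / |B|` against all clusters, counted per precluster
(each precluster is clustered independently; with <= 50 preclusters and
Omega_r = 1e-3 the dataset-wide false-positive probability stays below 5%).

## Algorithm

1. **Dereplication** collapses identical reads; every stage works on unique
   sequences weighted by abundance.
2. **Preclustering**: coarse 3% single-linkage components (substitution
   distance; indels excluded), computed once with a provisional uniform-rate
   score matrix. A k-mer screen (distinct 6-mer overlap, slack 0.5) plus
   union-find avoids the all-pairs alignment. Chaining is desirable: an
   error >3% away from every other read of its genotype is wildly improbable.
3. **Divisive clustering** per precluster: start from one cluster; repeat
   {split off the most statistically inconsistent family; alternate genotype
   updates and reassignment sweeps to a fixed point} until both Bonferroni
   tests pass. Reassignment sends each sequence to the cluster maximizing
   rho * lambda (expected reads of that sequence), computed synchronously
   against sweep-start rho. Families significant under the abundance p-value
   take priority as seeds; otherwise the family attaining lambda* in a
   read-significant cluster seeds. Only the seeding family's reads move;
   everything else relocates in subsequent sweeps.
4. **Outer alternation**: T starts at the pooled MLE under the trivial
   one-cluster-per-precluster partition, then clustering and pooled
   re-estimation (`T_ij = N_ij / N_i`, read-weighted, diagonal by
   normalization) alternate until `max |T' - T| < 1e-9`, T revisits a
   previous value (detected by hashing the matrix rounded to 12 significant
   digits), or 10 rounds elapse (warning).

Alignments use scores `5 + ln T` (natural log; diagonal ~5, worst mismatch
around -6, comparable to BLAST NUC.4.4), linear gap penalty -4 and
homopolymer gap penalty -1, charged per gap column. A gap column is a
homopolymer gap iff the base opposite the gap equals that strand's two
preceding bases -- the indel modifies a run of length >= 3, the regime
where pyrosequencer slippage actually occurs. The rule is path-independent,
so the DP stays exact. Requiring a genuine run matters: the -4 plain gap
was chosen (per the source method's own argument) so a gap pair (-8) never
beats a mismatch (>= -6), but a -1/-1 *homopolymer* gap pair (-2) outscores
any mismatch rarer than e^-7 ~ 9e-4. If two-base runs qualified, every rare
substitution at a run junction would be absorbed into gap columns, hiding
it from lambda and biasing the rare error-rate estimates down by 15-20%;
with the run>=3 rule the residual bias is ~1-2%. Traceback ties prefer
substitutions over gaps (diagonal > gap-in-read > gap-in-genotype), for
determinism.

## Numerical choices

- `p_y` uses the regularized-incomplete-beta binomial survival function and
  `expm1(rho*log1p(-lambda))` for the conditioning term: stable for lambda
  down to ~1e-8 and rho ~ 1e6. lambdas are accumulated in log space;
  a lambda that underflows entirely is clamped and yields p = 0
  (unambiguously significant).
- `q_a` enumerates gamma matrices best-first from a priority queue ordered
  by descending lambda_gamma (children of a gamma add one error, so the pop
  sequence is monotone and every gamma above the threshold is reached).
  Completion gives the exact tail. Each partial sum also gives a
  monotonically decreasing *upper bound* on q, so when q is astronomically
  small -- precisely the regime where completion is infeasible -- the
  enumeration stops as soon as the bound falls below the decision threshold.
  An expansion budget (default 1e7) errors out otherwise. The quoted
  O(L^11) precomputation with base-composition interpolation is not
  implemented; exact per-genotype computation is used.
- MLE off-diagonals are floored at `max(1/(N_i+1), 1e-8)` (rows then
  re-normalized) so zero counts never produce zero rates, which would break
  both the log-scores and lambda. A base absent from every genotype gets a
  floor row plus a warning. Convergence is tested on the floored,
  normalized matrices.
- The cluster "consensus" is the modal sequence: the most-abundant indel
  family's most-abundant member (ties lexicographic). It is stable, always
  a real observed sequence, and equals any column-wise consensus whenever
  one sequence dominates.
- The error-free family never seeds a split (it would duplicate the
  genotype) and is excluded from the abundance significance test; the
  read p-value covers its cluster regardless.
- Synchronous reassignment can ping-pong near-tied reads as rho flips; the
  inner loop therefore also terminates on a revisited partition state, with
  a 100-sweep cap as backstop.

## Defaults

| Parameter | Default | Meaning |
|---|---|---|
| Omega_a | 1e-40 | abundance-test joint significance; very small values compensate early-round PCR resampling in real data (results there were robust down to 1e-100) |
| Omega_r | 1e-3 | read-test joint significance; governs singletons |
| precluster cutoff | 0.03 | single-linkage substitution distance |
| gap / homopolymer gap | -4 / -1 | alignment penalties |
| tol, max rounds | 1e-9, 10 | outer-loop convergence |
| context | off | 192-rate model; risk of overfitting on small data |

## The simulator

`simulate` draws reads i.i.d. per genotype: per-site multinomial
substitutions from a true T (complement-symmetric by default, six pair
rates log-spaced 2e-4..2e-3, the range typical of PCR+pyrosequencing);
per-site indels at 5e-4, multiplied 4x inside homopolymer runs (insertions
uniform, deletions of the site's base) -- indels exercise the indel-family
machinery even though inference ignores them. The homopolymer multiplier
and the indel rate are package choices at the scale reported for 454
chemistry. An optional two-stage scheme (errors drawn on M template
molecules, reads resampled from templates) mimics early-PCR lineage
overdispersion and is off by default.

What the simulator does *not* emulate: chimeras, quality variation along
the read, position-dependent error rates, flowgram-specific noise, or
amplification bias. A green recovery test therefore establishes correctness
of the inference machinery under its own model assumptions, not robustness
to every real-data pathology.

## Known limitations

- Sequences differing only by indels are one genotype by construction.
- A single rare SNP at a junction of two homopolymer runs of length >= 3
  (e.g. `...CCCAAA...` with the junction base toggling) is
  indistinguishable from a deletion-insertion pair; the -1 homopolymer
  penalty then hides the substitution in gap columns and the pair merges.
  This mirrors the pathological-alignment false negatives reported for
  real 454 control data; the run>=3 rule makes it rare (~1% of random SNP
  placements) but cannot eliminate it, because the two sequences genuinely
  are one indel pair apart.
- The abundance statistic assumes reads are independent; oversampled PCR
  (template resampling) inflates the tails, which is why very small
  Omega_a values are the recommended default for real data.
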