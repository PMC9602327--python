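# Methods

This note documents the models and numerical choices behind `anv`: what
is computed, under which conventions, and what the synthetic benchmarks
do and do not demonstrate.

## The accumulated natural vector

A protein sequence of length $N$ over the fixed alphabet order
$A,R,N,D,C,E,Q,G,H,I,L,K,M,F,P,S,T,W,Y,V$ is mapped to 250 numbers: the
20 residue counts $n_\alpha$, 20 mean positions $\zeta_\alpha$, 20
variances $D_\alpha$ and 190 pairwise covariances
$\mathrm{cov}(\alpha,\beta)$ of the accumulated occupancy curves
$\tilde I_\alpha(k)$ (see the README for the formulas). Conventions:

- **Positions are 1-based** and all sums over $k$ run over $1..N$; the
  worked example in the test suite forces exactly this indexing.
- **Zero-count convention.** For a residue absent from the sequence the
  defining ratios divide by zero; we set $\zeta_\alpha = D_\alpha =
  \mathrm{cov}(\alpha,\cdot) = 0$. This matches the block-sparsity of the
  worked example and keeps vectors of different sequences comparable.
- **Covariance block order** is lexicographic over the alphabet order
  (pair $(\alpha,\beta)$ with $\alpha$ strictly earlier): $(A,R), (A,N),
  \dots, (Y,V)$.
- The centering constant $\theta_\alpha = \frac1N\sum_k \tilde
  I_\alpha(k)$ is deliberately distinct from the mean position
  $\zeta_\alpha$ (they differ by the factor $n_\alpha/N$); it exists only
  inside the variance/covariance computation and is not a vector
  component.
- All arithmetic is double precision; the whole 20×20 covariance matrix
  is computed as one Gram product of the centered curve matrix, so the
  Cauchy–Schwarz bound $|\mathrm{cov}(\alpha,\beta)| \le
  \sqrt{D_\alpha D_\beta}$ holds to rounding.

**Sanitization.** Real protein FASTA files contain ambiguity codes
(B, Z, X, U, O, J, `*`, gaps). Two explicit policies are offered:
`strict` (default) rejects such sequences naming the offending character
and position; `drop` deletes the characters before indexing and logs a
warning, because dropping shifts every downstream position and must
never be silent. No policy is hidden in between.

Vector tables are written as TSV with 12 significant digits — the
downstream LP feasibility test is sensitive to rounding, so round-trip
error is kept near machine precision.

## Convex-hull disjointness by LP feasibility

Two families' hulls intersect iff some convex combination of one point
set equals a convex combination of the other. That is a linear
feasibility problem in the $n+m$ combination weights with $k+2$ equality
constraints, solved with `scipy.optimize.linprog` (HiGHS, zero
objective). Hulls are never constructed; the test costs one LP per pair
even in 250 dimensions.

Numerical choices:

- **Conditioning.** ANV coordinates span orders of magnitude (counts of
  a few hundred vs. covariances near zero). Before the solve, the union
  of the two point sets is centered and each dimension is scaled to unit
  maximum absolute value; dimensions with zero range across the union
  are dropped (both combinations match there identically). Hull
  intersection is invariant under any shared per-dimension affine map,
  so the verdict is unchanged while the LP becomes well scaled. An
  invariance test confirms verdicts are stable under random joint
  rescalings over four orders of magnitude.
- **Tolerance.** Default feasibility tolerance $10^{-8}$ on the scaled
  coordinates (configurable); the solver's primal/dual feasibility
  tolerances are set to it. No tolerance is stated by the method's
  formulation itself, so borderline pairs are tolerance-sensitive by
  nature.
- **Indeterminate is an outcome, not a guess.** If HiGHS neither returns
  a feasible point nor proves infeasibility, an
  `IndeterminateHullError` is raised and counted separately in pair
  summaries, never silently mapped to a verdict.
- Duplicate points are retained (harmless to the hull).

Correctness is checked against an exact 2D computational-geometry oracle
(shapely polygon intersection) on 200 seeded random instances, plus
symmetry and affine-invariance properties; a 2D oracle suffices because
the LP formulation is dimension-generic.

The family-level distance is the Euclidean distance between hull
centroids (arithmetic means of the point sets). It is a pseudometric on
families: symmetric, zero self-distance, triangle inequality (distinct
families can in principle share a centroid).

## LDA and MMC projection

For visualization and 2D hull analysis of a family pair, two supervised
projections are provided. With class scatter sums $S_w = \Sigma_0 +
\Sigma_1$ (within) and $S_b = (\mu_0-\mu_1)(\mu_0-\mu_1)^\top$
(between):

- **LDA** maximizes the Rayleigh quotient $\omega^\top S_b \omega /
  \omega^\top S_w \omega$; we solve the generalized symmetric
  eigenproblem $S_b v = \lambda S_w v$ rather than forming
  $S_w^{-1}S_b$, and reject inputs whose $S_w$ condition number exceeds
  $10^{12}$ with an explicit small-sample-size error naming MMC as the
  remedy. This regime is the rule, not the exception, for ANV data: two
  families with at most 250 sequences combined cannot have full-rank
  $S_w$ in 250 dimensions.
- **MMC** maximizes $\mathrm{tr}\,\omega^\top(S_b-S_w)\omega$ over
  orthonormal $\omega$ — the top eigenvectors of the symmetric matrix
  $S_b - S_w$ — and involves no inverse, so it succeeds for any sample
  size.

Because $S_b$ has rank one for two classes, only the leading direction
is determined by either criterion; a requested second direction is the
next eigenvector of the same matrix and the result carries a
`rank_deficient` flag. Eigenvector signs are fixed by making the
largest-magnitude component positive, so projections are reproducible
across platforms.

## Classification

1-nearest-neighbor under Euclidean ANV distance, evaluated leave-one-out:
each vector is classified against all others, self excluded. A shared
train/test protocol in which a vector may match itself trivially yields
100% accuracy whenever vectors are distinct, so self-exclusion is the
default and the report names its protocol; the naive variant is
available as `include_self` for comparison. Distance ties go to the
smallest training index; for general $k$ a majority vote breaks ties
toward the class earlier in sorted class order. The implementation is an
exhaustive distance scan — training sets are family-sized, and the
deterministic tie behavior is part of the contract.

## Clustering and trees

Families are summarized by their hull centroids and the centroid
distance matrix feeds:

- **single-linkage** ("shortest distance") agglomeration via
  `scipy.cluster.hierarchy`, cut at a requested cluster count; merge
  heights are monotone by construction. Tie-breaking among equal linkage
  distances follows scipy's deterministic internal ordering (ties are
  measure-zero for continuous distances).
- **neighbor joining** via `skbio.tree.nj`; exact on additive matrices
  (verified on a 4-taxon matrix built from known branch lengths).
  Negative branch lengths that can arise on non-additive inputs are
  clamped to zero.

For reporting, centroids can be projected onto their top-2 principal
directions. This is a visualization aid for the cluster table — an
unsupervised choice of axes, not LDA/MMC — and is labeled as such.

## Synthetic data

The generator draws families of i.i.d. sequences: per-family residue
compositions from a symmetric Dirichlet, sequence lengths uniform on
[200, 800] (the scale of typical proteins), residues i.i.d. from the
composition. The `separation` knob in $[0,1]$ maps to the Dirichlet
concentration $c(s) = 0.2 \cdot 100^{\,1-s}$ — near-uniform, overlapping
compositions at small $s$, spiky nearly disjoint compositions at $s=1$ —
with $s=0$ short-circuited to the exact uniform composition. A master
seed derives per-family seeds (`seed + 1 + index`) so any family
regenerates independently; FASTA output is byte-identical for identical
inputs.

The benchmark used by the acceptance-level tests is 4 families × 50
sequences at separation 1: all 6 hull pairs disjoint, leave-one-out 1-NN
accuracy ≥ 0.95, and a label-shuffled control within binomial noise of
1/4. These sizes keep the full suite to a few seconds while exercising
the 250-dimensional LPs on realistic point-set sizes.

**What passing does and does not show.** The generator produces
compositional structure only — no substitution process, indels, domain
architecture, shared ancestry or length–composition coupling. Passing
demonstrates that the machinery is correct and that compositionally
separated families behave as the convex-hull principle predicts; it does
not certify accuracy or disjointness rates on real proteomes, where
family differences are subtler. Real datasets (RefSeq/UniProt FASTA, one
file per family) can be run through the identical CLI commands as
optional external analyses.

## Known limitations

- Hull verdicts near the feasibility tolerance are inherently
  tolerance-dependent; the indeterminate outcome exists precisely to
  keep summary fractions honest.
- LDA on raw ANV data almost always requires more sequences than
  dimensions; MMC is the practical default for 2D views.
- The embedding is composition- and dispersion-based: sequences with
  identical residue multisets in similar arrangements map close together
  regardless of homology.
- Multi-class (>2) discriminant projection and bootstrap support for
  trees are out of scope.
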