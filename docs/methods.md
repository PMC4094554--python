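# Methods

## Dependency metrics

### Maximal information coefficient (MIC)

For n paired observations, every grid of nx columns by ny rows with
`nx·ny ≤ B(n)` induces a discrete joint distribution whose mutual
information, normalised by `log min(nx, ny)`, lies in [0, 1].  MIC is the
maximum of this *characteristic matrix* over grid sizes and grid-line
placements.  The budget is `B(n) = max(4, ⌊n^α⌋)`; the floor of 4 keeps the
minimal 2×2 grid admissible at small n.

Two estimators are implemented:

- **Heuristic** (default): for each ny, the y axis is split into ny
  equal-frequency rows; the x axis is then partitioned optimally by dynamic
  programming with column boundaries restricted to `c·nx_max` approximately
  equal-frequency "superclump" cut points.  The DP maximises
  `H(P) − H(P,Q)`, which is additive over columns, so the recurrence
  `f_l(i) = max_j f_{l−1}(j) + g(j, i)` is exact given the boundary set.
  Both orientations are computed and the elementwise maximum taken.  Every
  grid the heuristic evaluates is a genuine grid, so its score is a lower
  bound of the true MIC.  Defaults α = 0.6 and c = 15 follow the original
  MINE statistic's published defaults.
- **Exhaustive** (oracle): enumeration of *all* boundary placements for all
  admissible (nx, ny).  Exponential in n and restricted to n ≤ 16; it
  defines ground truth for the property tests (heuristic ≤ exhaustive on
  every dataset, equality when the optimum is an equipartitioned grid).

Both operate on ranks only, making MIC invariant under strictly monotone
transforms of either variable.  Ties are broken by the stable order of
sample index when forming partitions; a constant vector yields score 0
rather than an error.  The hot loops avoid transcendental calls by a
precomputed `m·log m` table (the `log n` terms cancel within a column), and
are JIT-compiled with numba.

### Mutual information and DPI pruning

MI is the plug-in estimate in nats on equal-frequency bins, with
`⌈n^(1/3)⌉` bins by default — a bias/variance compromise that grows slowly
with sample size.  `MI(x, x)` equals the entropy of the binned variable
(`log n_bins` when n is a multiple of the bin count).  A Gaussian-kernel MI
estimator is deliberately out of scope; the binned estimator is documented
as a divergence from ARACNE's kernel default.

Data-processing-inequality pruning removes, within each fully connected
triangle, any edge with `MI < (1 − t)·min` of the other two, where t is the
tolerance.  The tolerance is interpreted *fractionally*, under which t = 1.0
(the setting this pipeline mirrors) disables pruning entirely and t = 0 is
the strict DPI.  All triangles are scanned against the original weights
before any edge is removed.

### Linear regression

Ordinary least squares; the reported r is the Pearson correlation, so the
slope and r agree in sign.  A negative slope against the regulator marks
inverse correlation — the expression signature expected of a transcript
degraded by its regulator.

### Regulator-vs-all scoring

Only regulator rows are scored against all genes (not all-vs-all); the
regulator is never scored against itself.  LR is vectorised across genes;
MI and MIC are computed per pair.

## Permutation FDR

The null is *pooled*: each of n_perm permutations shuffles the regulator
vector and scores it against one randomly chosen non-regulator gene.  After
rank-based grid construction the null distribution is approximately
exchangeable across genes, so the pooled sample stands in for per-gene
nulls at a fraction of the cost.  For observed score s among m genes with a
null of size N,

    q(s) = [(#null ≥ s + 1) / (N + 1)] · m / max(1, #observed ≥ s),

clipped to [0, 1] and monotonised by a suffix minimum over descending
scores, so q is non-increasing in the score.  The +1 pseudo-count is the
standard permutation correction that avoids q = 0; it makes the smallest
attainable q equal to `m / ((N+1)·k)` at k discoveries, which is why the
default n_perm = 10⁴ is the practical minimum for resolving q ≤ 0.01 on a
500-gene matrix with a handful of true targets.  Published analyses of this
kind have used permutation counts several orders larger; that is equally
valid here via `--n-perm` but unnecessary for the bundled scenarios.

The hypergeometric overlap test reports the upper-tail probability
`P(overlap ≥ k)` for two gene sets drawn from a finite universe (identical
to R's `phyper` upper tail); it is verified against exhaustive subset
enumeration for all universes up to size 12.

## Gene-set enrichment (GSEA)

Walking the ranked list, members increment the running sum by
`|score|^p / Σ|score|^p` and non-members decrement it by `1/(N − Nh)`; the
enrichment score is the signed extremum and the sum returns to 0 at the end
of the list.  With p = 0 this equals the classical two-sample KS statistic
on member/non-member ranks (cross-checked against an independent KS
implementation).  When the maximal positive and negative deviations tie in
magnitude exactly, the positive one wins — matching the convention used in
the hand-walk oracle.  The default weight is p = 1 (the weighted variant
customary for score-ranked lists); p = 0 is available.

Because the input is a single ranked list rather than per-sample phenotype
labels, the null permutes gene labels: random same-size member sets drawn
from the list.  NES divides ES by the mean |null ES| of matching sign.  The
nominal p compares the observed ES with the same-sign null pool
(pseudo-counted).  The FDR q is a conservative variant of the pooled-null
procedure: the numerator tail fraction is taken over the *entire* pooled
null NES sample with a +1 pseudo-count, the denominator over the observed
NES values; with a single gene set this reduces to `(#null ≥ NES + 1)/(n_perm·n_sets + 1)`.

## ARE motif scanning

The 13-bp consensus `WWWUAUUUAUUUW` is expanded per IUPAC (W → A or U).
Scanning is strand-as-given (3′UTRs are sense strand), case-insensitive,
with T ≡ U on both sides; N or any other ambiguity code in the *sequence*
never matches (conservative calling).  Overlapping windows count as
distinct copies by default — the ARE-cluster convention is ambiguous, so a
greedy non-overlapping mode is provided for sensitivity analysis.
Coordinates are 1-based inclusive.  The target shortlist requires ≥ 2
copies by default.

## Target filtering and network assembly

The final list is a pure intersection — q ≤ threshold, ARE copies ≥
minimum, negative LR slope (optional), and membership in ≥ 1 configured
annotation term — applied in a fixed order for reporting but mathematically
order-independent; every gene carries a per-filter provenance record.
Genes without a 3′UTR sequence fail the ARE filter (logged), mirroring how
absence from an ARE catalogue is treated conservatively.  The annotation
filter is a plain term-set intersection on a user-supplied table; no
ontology traversal is performed, since term lists are release-dependent
user input.  The union graph over regulators is a directed
regulator→target graph without self-edges, exported as Cytoscape SIF with a
fixed interaction label and sorted, deterministic line order.

## Assay computations

**2^−ΔΔCT.**  ΔCt = Ct_target − Ct_reference per condition;
ΔΔCt = ΔCt_treated − ΔCt_control; fold change = 2^−ΔΔCt.  Amplification
efficiency is assumed to be exactly 2; replicate ΔCt values are averaged
within condition.

**Decay kinetics.**  First-order decay gives `ln a(t) = −k·t + c`; k is fit
by pooled OLS on log abundances after normalising to the t = 0 mean
(matching relative qRT-PCR quantification), and t½ = ln 2 / k.  Log-linear
OLS is used rather than nonlinear exponential fitting because three time
points cannot constrain additional parameters.  k ≤ 0 is reported as "no
detectable decay" with undefined half-life rather than an error.  Condition
comparison tests the condition × time interaction coefficient in the joint
log-linear model (two-sided t-test), with Benjamini–Hochberg control across
genes; this slope-interaction test is the package's stand-in for two-step
polynomial time-course regression frameworks, reproducing their statistical
role (flagging transcripts with altered decay rates) without their
model-selection machinery.

## Synthetic study conditions

The generators emulate the statistical roles of a large microarray
compendium and its companion assays:

- **Expression**: the regulator is N(0, 1) across samples on the log scale;
  linear targets are `slope·regulator + ε` with slope −2 by default
  (inversely correlated); nonlinear targets are centred even functions of
  the regulator (parabola x²−1, cosine, |x|), whose Pearson correlation
  vanishes by sign symmetry while MIC saturates — the contrast on which the
  metric comparison rests; background genes are independent N(0, 1).
  Gaussian log-scale values are assumed because the upstream normalisation
  of real array data is out of scope.  Defaults (500 genes × 200 samples,
  5 planted targets, noise SD 0.5) define the bundled demo scenario; they
  are a deliberately scaled-down analogue of a ~10⁴-gene × ~200-sample
  compendium, sized so the full pipeline runs in minutes.
- **3′UTRs**: uniform base composition with the requested number of planted
  motif instances (each W drawn independently); candidate sequences are
  rejection-sampled until the scanner reports exactly the planted hits, so
  the background is guaranteed motif-free and truth tables always agree
  with the scanner.
- **Validation gene sets**: a chosen number of planted targets plus decoys
  drawn from the rest of the universe, standing in for knockout-derived
  up-regulated/stabilised sets.
- **Decay**: `exp(−ln 2·t/t½)` at t = 0, 2, 4 h with mean-1 multiplicative
  lognormal noise (abundances are positive ratios), renormalised so the
  mean at t = 0 is exactly 1.  The default scenario pairs a 2.6 h control
  half-life with a 5.2 h knockdown half-life.
- **qPCR**: four Ct values per gene encoding a planted ΔΔCt exactly, with
  optional Gaussian Ct noise.

What the generators do *not* emulate: probe-level intensities and array
normalisation artefacts, correlated background co-expression modules,
multiple interacting regulators, heterogeneous 3′UTR lengths and base
composition, or amplification-efficiency variation.  Passing tests
therefore demonstrate correctness of the estimators and the recoverability
of planted structure under idealised noise — not performance on real
compendia, where correlated backgrounds inflate null dependencies and the
FDR calibration would need the full permutation machinery.

## Numerical and reproducibility choices

- Every stochastic routine takes an explicit seed; the pipeline derives one
  seed per stage from the master seed by hashing the stage name, and the
  run manifest records SHA-256 hashes of all outputs so byte-identical
  reruns are verifiable.
- Ranked lists break score ties lexicographically on the gene identifier.
- MIC scores are clipped to [0, 1] against float round-off; equality
  comparisons between the heuristic and the oracle hold to ~1e-12.
- Degenerate inputs are handled explicitly: constant vectors (MIC/MI 0,
  LR error for constant x), empty gene sets and sets covering the whole
  list (errors), all-equal abundances (no-decay flag), zero null
  exceedances (pseudo-count).

## Known limitations

- The binned MI estimator differs from kernel-based estimators; absolute MI
  values are not comparable across estimators, although rankings largely
  are.
- The pooled permutation null assumes gene exchangeability under the null;
  strong heteroscedasticity across genes would warrant per-gene nulls.
- The GSEA FDR is conservative by construction (whole-pool numerator); with
  many gene sets the standard sign-stratified pooling would be sharper.
- MIC detects dependence, not causality or directionality; edge direction
  in the exported network encodes the regulator-vs-all scoring design, not
  causal inference.
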