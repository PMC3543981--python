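# Methods

## The model

admixkit estimates, for each target individual *i*, the fraction
*q<sub>ik</sub>* of their genome derived from each of *K* labeled
ancestral populations.  Genotypes *g<sub>ij</sub>* ∈ {0, 1, 2} at
biallelic SNP *j* count alternate alleles.  Conditional on the ancestry
vector *q<sub>i</sub>* (a point on the K-simplex) and the population
alternate-allele frequencies *f<sub>kj</sub>*, each genotype is

  g<sub>ij</sub> ~ Binomial(2, p<sub>ij</sub>),  p<sub>ij</sub> = Σ<sub>k</sub> q<sub>ik</sub> f<sub>kj</sub>,

independently across sites (an unlinked-marker assumption appropriate
for LD-pruned panels).  The log-likelihood, dropping the binomial
constant, is Σ g ln p + (2−g) ln(1−p) over observed genotypes; missing
genotypes contribute nothing.

**Supervised estimation.**  Reference individuals have their membership
fixed at the indicator vector of their documented population.  Target
rows and allele frequencies are then jointly maximized by EM.  Because
a reference individual of population *k* has p<sub>ij</sub> =
f<sub>kj</sub> exactly, its contribution to the EM frequency update
collapses to its allele counts, and the joint fit is computed — exactly,
not approximately — as an EM over the targets alone with the panel
folded in as K×J count matrices.  Panel size therefore does not affect
per-iteration cost.  A `fixed_F` mode instead freezes frequencies at
panel count frequencies (+0.5 pseudocount), decoupling the problem per
target; it backs the fast leave-one-out path and known-frequency
oracles.

**Optimization.**  The engine takes plain EM steps (the block updates
classical model-based clustering programs use), wrapped in a SQUAREM
extrapolation: two EM steps define a secant direction, an extrapolated
point is projected back to the feasible region, stabilized by one more
EM step, and accepted only if its log-likelihood has not dropped —
otherwise the plain double-step is kept.  The iteration is therefore
exactly monotone, which the test suite asserts, while converging an
order of magnitude faster than plain EM.  The inner sums run in a fused
numba kernel (a pure-numpy reference implementation is kept and
parity-tested to 1e−12).

**Convergence.**  Iteration stops when the per-EM-step log-likelihood
gain falls below `tol`, by default 1e−8 per observed target genotype
(floored at 1e−8), with `max_iter` 2000 EM-equivalent steps.  The
per-genotype scaling keeps stringency comparable across problem sizes.
The default is deliberately tight: admixture components whose truth is
on the simplex boundary drain geometrically slowly, and a loose
tolerance leaves systematic spurious mass (~1e−2 at desk scale) that
masquerades as real ancestry signal and corrupts both bootstrap SEs and
denoising.  Frequencies are clamped to [1e−6, 1−1e−6] to guard the log
domain.

## Uncertainty and denoising

Standard errors come from a moving-block bootstrap over markers:
contiguous blocks of `block_len` markers (within chromosomes) are
resampled with replacement to the original marker count, the supervised
fit is re-run per replicate (warm-started from the point estimate,
which changes nothing statistically), and SE<sub>ik</sub> is the
across-replicate standard deviation (n−1 denominator).  The default
`block_len` is 1 because panels are LD-pruned; longer blocks preserve
residual local dependence.  The module default of 200 replicates
follows common bootstrap practice; the shipped simulation studies use
40 replicates, which resolves SEs of ~0.005–0.01 to ~12% relative error
— ample for the 2·SE retention rule — at desk-scale runtime.

Denoising implements the second pass: population *k* is retained for
individual *i* iff q̂<sub>ik</sub> − 2·SE<sub>ik</sub> > 0, i.e. the
~95% lower confidence bound excludes zero; otherwise the population is
removed from that individual's reference set and proportions are
re-estimated over the retained populations (frequencies re-estimated in
the second pass; a flag reuses first-pass frequencies).  Excluded
populations get exact zeros.  If no population passes the rule — only
possible for degenerate inputs with SEs comparable to 1/K — the single
largest component is retained as a guard.  Individuals with identical
retained sets are refit in one grouped run (an exact equivalence under
fixed frequencies, a near-equivalence otherwise; a flag forces
per-individual runs).  SEs are not recomputed after denoising.

## Panel construction

Reference panels are built stepwise.  A seed stage clusters
well-differentiated cohorts unsupervised into K groups; clusters map to
documented labels by Hungarian assignment on the K×K mean-proportion
matrix (a deterministic formalization of by-eye matching), and members
are admitted at own-cluster proportion ≥ 0.9.  Expansion stages add one
population at a time: anchor individuals get fixed membership in the
new population, remaining candidates are scored by a supervised fit and
admitted at strictly > 0.9.  The two boundaries (≥ vs >) are kept
deliberately as stated in the construction narrative they reproduce;
both are configurable.  Admission order matters — recipes are explicit
and never inferred.  Every candidate lands either in the panel or in an
exclusion report with its own-cluster proportion.

## Validation battery

* **IBS distance**: D<sub>il</sub> = 1 − mean over jointly observed
  SNPs of (2 − |g<sub>i</sub> − g<sub>l</sub>|)/2; bounded in [0, 1], a
  metric on genotype vectors.
* **PCoA**: classical scaling (double-center −½D², eigendecompose,
  scale eigenvectors by √eigenvalue); variance explained is reported
  against the positive-eigenvalue total.  Cross-checked against
  scikit-bio's implementation in tests.
* **Fst**: Hudson's estimator with ratio-of-sums combination across
  SNPs — sample-size robust and equipped with a clean simulation
  oracle.
* **Distance-variance test**: a permutation pseudo-F (PERMANOVA-style)
  of the grouping on the distance matrix; reports R² = 1 −
  SS<sub>within</sub>/SS<sub>total</sub> and p = (1 + #{F<sub>perm</sub>
  ≥ F<sub>obs</sub>})/(n<sub>perm</sub> + 1).  Cross-checked against
  scikit-bio's permanova.
* **Leave-one-out**: each panel member is re-estimated against the
  panel minus itself, using count frequencies recomputed with that
  member removed (the fixed-frequency path; removing one member
  perturbs a joint fit negligibly, and this keeps 2,500 refits cheap).
* **SE-vs-marker-count curves** and **trio deviation** (child minus
  parental-average proportions) quantify, respectively, marker-panel
  saturation and end-to-end estimation error.

## The simulator

Population frequencies follow the Balding–Nichols model: ancestral
p<sub>j</sub> ~ Uniform(0.05, 0.95), then f<sub>kj</sub> ~
Beta(p(1−F<sub>k</sub>)/F<sub>k</sub>, (1−p)(1−F<sub>k</sub>)/F<sub>k</sub>)
with per-population drift F<sub>k</sub>.  Under this star-shaped model
the expected pairwise Hudson Fst is ≈ (F<sub>a</sub>+F<sub>b</sub>)/2.
The default six-population drift ladder {Europe 0.09, Africa 0.25,
America 0.25, EastAsia 0.09, Oceania 0.34, CentralAsia 0.03} is a
least-squares star fit to observed continental pairwise Fst values
(range ~0.03–0.30), rounded so the Europe–America pair lands at 0.17.
A star model cannot reproduce every observed pair (America–EastAsia is
the worst miss: shared drift is not representable), and it places
low-drift populations near the ancestral centroid — which also makes
the Central-Asia analogue *more* confusable with a Europe/America
mixture than real Central Asians are with European/Native-American
admixture.  Passing tests on these synthetics therefore demonstrate
correct estimation under the stated model, not robustness to LD,
genotyping error, or tree-like shared drift, none of which are
simulated.

Genotypes are Binomial(2, QF) at unlinked sites; offspring genotypes
draw one allele per parent per site (unlinked transmission).  All
generators are bit-reproducible under a seed.

## Study conditions for the quantitative checks

The shipped simulation studies (also recomputed by
`scripts/acceptance.py`) use: J = 16,443 markers across 22 chromosomes;
100 admixed targets per scenario (two-way Europe/America 0.5/0.5;
three-way Europe/America/Africa 0.2/0.05/0.75); a reference panel with
the continental composition Europe 1335, Africa 366, America 47,
EastAsia 453, Oceania 16, CentralAsia 296; bootstrap with 40 replicates
at block length 1.  At these conditions the mean denoised estimates
recover the simulated mixtures to ~0.005 and non-simulated populations
retain mean contributions at the few-10⁻⁴ level; per-individual
standard errors are ~0.01, matching the scale such analyses report.

## Known limitations

Unsupervised fits are only locally optimal (different seeds can land on
different modes for weakly separated data); the supervised path is the
intended workhorse.  The bootstrap treats markers as the resampling
unit and so does not capture reference-sampling variance beyond what
markers express.  No multiple-testing adjustment is applied across the
K retention tests per individual, matching the procedure being
reproduced.  PLINK input is read-only; phased data, dosages and local
ancestry are out of scope.
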