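# Methods

## Data

The packaged tables describe 27 sulfonamide derivatives with proven
anticancer activity against the HCT-116 human colon cancer line.
`table1` holds seven computational logP estimates per compound (iLogP,
XLogP3, WLogP, MLogP, Silicos-IT LogP, their consensus, and KOWWIN
logP); `table2` holds the chromatographic measurements — the CHI
retention indices from IAM and C18 gradient HPLC and their logk_IAM /
CHI-logD transforms, three extrapolated logk_w values (C8, CN and phenyl
columns), the computed pKa, and the pIC50 potency.  Values are stored as
printed (two decimals; pKa one decimal); compound identifiers are the
series labels "1".."27" kept as strings.  All chromatography was run at
pH 7.4, so the chromatographic indices are distribution-coefficient
(logD-like) measures of the partly ionized species, while the
computational estimates describe the neutral molecule — the structural
reason the two families separate in every analysis.

The twelve-column analysis panel joins the seven computational estimates
with the five chromatographic indices.  The raw CHI_IAM and CHI_C18
columns are excluded (they are positive affine transforms of logk_IAM
and CHI_logD and therefore rank-identical with them); pKa and pIC50 are
excluded because they are not lipophilicity measures.  pIC50 can be
appended (`lipophilicity_panel(include_pic50=True)`) for the clustered
heat map, where its proximity to the chromatographic cluster is itself a
finding.  pKa is never clustered by default.

## Transforms

`logk_IAM = 0.045·CHI_IAM + 0.42` and `CHI logD = 0.0525·CHI_C18 −
1.467` are fixed calibrations taken as constants; the package does not
re-derive them from standard-compound retention data.  Consensus logP is
the arithmetic mean of the five SwissADME predictions.  When audited
against the packaged tables the transforms reproduce the printed columns
exactly at two decimals; the consensus differs by at most one rounding
unit (0.01) for a few compounds because the printed inputs are
themselves rounded.  Comparisons against printed values round half away
from zero, the convention of the printed tables, with a small pre-round
at 1e−8 so decimal halves stored inexactly in binary still round up.

## Sum of ranking differences

For a compound-by-measure table, each column is ranked over compounds
(ties as average ranks) and compared with the ranking of the row
averages; SRD is the sum of absolute rank differences, normalized by its
maximum (n²/2 for even n, (n²−1)/2 for odd) to SRD%.

Columns are scaled before the row average is taken, since the raw mean
would be dominated by the widest-scaled measure.  The default is
interval (min–max) scaling onto [0, 1], the customary preprocessing for
consensus-reference SRD; it is also the only choice among
{range, autoscale, none} that reproduces the known behaviour of this
panel on all counts — the consensus logP closest to the reference, the
CN/C18/Ph-derived indices furthest, and logk_IAM nearly tied with KOWWIN
logP.  Autoscaling remains available (`scaling="standardize"`); it
perturbs the reference enough to swap KOWWIN and CHI_logD near the tail.
Only the reference depends on this choice; per-column rankings are
scale-invariant.

Significance is judged against CRRN, the distribution of SRD between a
random permutation and a fixed reference.  For n ≤ 10 the distribution
is exact, computed by a bitmask dynamic program over value subsets
(equivalent to full enumeration of n! permutations, verified against
brute force up to n = 6).  For larger n a seeded Monte-Carlo sample is
used (default 10⁶ permutations, drawn in 2·10⁵-permutation blocks).  The
mean of the null is (n²−1)/3 — 242.67 for n = 27 — which the exact
method reproduces identically and the Monte-Carlo sample within
sampling error.  Empirical 5/25/50/75/95 percent points are reported
rather than a Gaussian fit; the support contains only even integers, so
quantiles are resolved no finer than 2 SRD units.

Robustness uses k-fold cross-validation (default k = 7, leaving out
about 1/7 of the compounds per fold: a seeded random partition,
27 → 4,4,4,4,4,4,3): each reduced table is rescaled, re-referenced and
rescored, giving k SRD% values per measure for box–whisker display, and
measures are grouped by two-sided Wilcoxon matched-pair tests on those
vectors (zero differences dropped; exact p by sign-assignment
enumeration up to 25 tie-free differences, normal approximation
otherwise).

## PCA and cluster analysis

Both operate on column-standardized data (mean 0, unit sample SD,
n−1 denominator), equivalent to analyzing the correlation matrix.  PCA
uses the singular value decomposition with a deterministic sign
convention (largest-magnitude loading per component positive).  Cluster
analysis is Ward linkage on Euclidean distances, applied to measures as
vectors over compounds (and symmetrically to compounds); it is backed by
scipy's linkage and verified against a Lance–Williams recursion in the
tests.  On the packaged panel, cutting the measure dendrogram at two
clusters separates the seven computational estimates from the five
chromatographic indices, with pIC50 joining the chromatographic side.

## PLS and validation statistics

PLS1 is implemented as NIPALS on autoscaled X and centered y.
Autoscaling is used because selected descriptor subsets are
heterogeneous in units; with as many latent variables as the rank of
centered X the fit equals ordinary least squares (a test pins this to
1e−8).  Predictions for new compounds apply the stored centering/scaling
and original-scale coefficients.

Validation follows the standard QSAR battery.  Training R² and
leave-one-out Q² (PRESS against the total sum of squares about the full
training mean, RMSE_CV = √(PRESS/n)) describe the fit; external
predictions are scored by Q²F1 (external residuals against the training
mean), Q²F2 (against the external mean), Q²F3 (per-n variance
normalized), RMSEP, and Lin's concordance correlation coefficient.
Degenerate reference sums of squares yield NaN plus an `undefined` flag,
never infinities.

## GA-PLS

Descriptor selection evolves fixed-length chromosomes of 5 distinct
descriptor indices with fitness = training R² of a 3-LV PLS fit
(population 500, per-gene mutation rate 0.1; a Q²loo fitness switch
exists for users).  Operators: tournament selection (size 2),
subset-preserving crossover — the child keeps the genes its parents
share and fills the remainder from their symmetric difference — per-gene
mutation with duplicate repair, elitism 1, and a stall stop (20
generations without improvement, cap 100).  Because a single GA run on
a 100-descriptor pool converges prematurely in a nontrivial fraction of
cases, the default configuration runs 3 independent restarts and refines
each run's best individual by steepest-ascent single-descriptor
exchange before the overall winner is refit and validated; both
safeguards are standard memetic practice in descriptor selection and are
exercised against synthetic ground truth in the tests (with 27
compounds, 100 candidate descriptors, 5 informative ones and 5% noise,
the exact subset is recovered in 18 of 20 fixed seeds).  Fitness values
are memoized per chromosome, which keeps the restarts cheap.

The train/test split (18/9 for 27 compounds) is a seeded random
partition post-processed so the compounds with the smallest and largest
endpoint values always sit in the training set, preventing extrapolation
in y during external validation.

y-randomization refits the selected-descriptor model on permuted
endpoints (default 200 permutations), recording R² and optionally Q²loo;
a real model must exceed essentially the whole permuted distribution.
The applicability domain uses hat-matrix leverages on the autoscaled
selected descriptors plus an intercept column, so training leverages sum
to p+1 = 6 and the centroid has leverage 1/n_train; the critical value
is the conventional h* = 3(p+1)/n_train and residuals are standardized
by the training residual SD with a ±3 band.

## Synthetic data

`make_descriptor_dataset` (defaults: 27 compounds, 100 descriptors, 5
informative, noise SD = 5% of signal SD, optional exchangeable
correlation) emulates a cleaned molecular-descriptor matrix driving a
linear endpoint; `make_lipo_table` (defaults: 27 compounds, 12 measures,
noise SD 0.3 against a standard-normal latent scale, slopes U(0.5, 2))
emulates a family of lipophilicity measures that all estimate one latent
property with different scales and error.  Both are pure functions of
their seed.  They deliberately omit features of real data — descriptor
block structure beyond exchangeable correlation, non-Gaussian noise,
nonlinearity, and measure-specific biases such as ionization effects —
so passing tests demonstrate that the algorithms recover known structure
under their own assumptions, not that real chromatographic data meet
those assumptions.

## Numerical and design notes

- Problem sizes used in tests and the bundled pipeline (10⁶ CRRN draws;
  GA demos at population 80–500 and 10–30 generations; 20-seed recovery
  studies) were chosen to make every stochastic assertion stable at
  fixed seeds while keeping a full run inside a few minutes on one core.
- All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline summary embeds the seed and a hash of the analysis settings,
  and reruns with the same seed are byte-identical.
- Ties: average ranks throughout; the CRRN null assumes tie-free
  permutations (even support), adequate because the packaged panel's
  reference ranking is tie-free.
- Exact Wilcoxon p-values require tie-free absolute differences; ties
  trigger the normal approximation.
- `drop_near_constant` uses sample variance with a 1e−8 default
  threshold on unscaled descriptors, mimicking routine descriptor
  cleaning; "near-constant" has no canonical definition.
- The GA-PLS statistics of the original study's own models are not
  reproducible here: they depend on a commercial descriptor matrix
  (alvaDesc) that is not redistributable.  The package accepts any
  user-supplied descriptor CSV in its place, and the synthetic generator
  provides ground-truthed stand-ins.

## Limitations

SRD conclusions on 27 objects are sensitive to the scaling convention
(see above) — the package exposes the choice rather than hiding it.  The
leverage AD assumes the selected descriptor block is well-conditioned;
exactly collinear selections are rejected.  PLS2 (multi-response),
nonlinear PLS, and ties-aware CRRN nulls are out of scope.
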