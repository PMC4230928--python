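# Methods

tigerscape implements an individual-based landscape-genetics workflow for a
territorial large carnivore sampled non-invasively (scat) across a
fragmented landscape: identify individuals from noisy replicate
microsatellite genotypes, quantify population structure and recent
migration, estimate detection-corrected occupancy from replicated sign
surveys, convert occupancy into a movement-cost surface, model corridors by
least-cost and circuit analyses, and test which spatial model best explains
genetic differentiation. This note records the models, the defaults and why
they were chosen, the numerical details, and what the synthetic-data tests
do and do not demonstrate.

## Synthetic data generator (`simdata`)

Because the workflow is validated on simulated data, the generator is
first-class code with a ground-truth ledger.

**Landscape.** Habitat is a union of circular patches placed on a ring so
patches are distinct connected components in a permeable matrix; covariates
(forest quality, prey index, disturbance) are Gaussian-smoothed noise fields
(kernel width 3 cells) loosely tied to habitat, so the PCA stage faces
realistically correlated covariates. Settlements occupy only the matrix and
can form an impermeable band.

**Metapopulation.** Forward-time Wright–Fisher with diploid individuals,
11 microsatellite loci by default, alleles as repeat counts. All populations
start from one ancestral pool with 4–12 alleles per locus, then drift under
a configurable migration matrix (rows: destination; diagonal = 1 − total
immigration fraction). Mutation follows the two-phase model: single-step
with probability 0.95, otherwise a geometric multi-step whose variance is 12
repeat units² (the same model assumed by the bottleneck test, so simulator
and test share one mutation model). The default mutation rate 1.5×10⁻³ per
locus per generation is typical for mammalian microsatellites and keeps
per-population allele counts near 5 and expected heterozygosity near 0.6
through the default run (Ne = 100 per population, 200 generations, pairwise
migration 0.003), which realizes pairwise F_ST of roughly 0.05–0.25 — the
range the analysis stages are designed for. F_ST at migration–drift balance
is governed by Nm, so the regimes used in the recovery experiments scale Ne
and m jointly (e.g. Ne = 150, m = 0.004, 300 generations for the
F_ST ≈ 0.15 migrant-power experiment).

**Migrants.** Planted after drift, immediately before sampling, so
"first generation" is well defined at sampling time: a gen-1 migrant is a
whole genotype copied from the source pool; a gen-2 individual receives one
allele per locus from a source parent and one from a destination parent.

**Non-invasive noise.** Each sampled individual yields replicate genotypes.
Within a replicate, each allele of a heterozygote drops independently with
probability 0.10 (one drop → false homozygote, two → missing locus); a
whole-locus failure rate of 0.07 per sample reproduces ~93% locus typing
success. These rates are plausible for scat DNA but are design choices, not
calibrated estimates; both are configurable.

**Detection histories.** Occupancy state is drawn once per grid (closure);
detections are Bernoulli(p) at occupied grids only; survey counts vary per
grid (3–35 by default; experiments cap at smaller counts for speed). The
per-survey detection default is 0.2, matching large-landscape sign surveys.

**What the simulations do not emulate:** genotyping artifacts other than
dropout (stutter, null alleles, contamination), spatially structured
detection heterogeneity, relatedness structure within populations beyond
random mating, and real geodesy (planar km only). Passing recovery tests
therefore demonstrates correctness of the estimators under their assumed
models, not robustness to every field artifact.

## Individual identification (`genotypes`)

Consensus calling mirrors replicate-PCR practice: accept a heterozygote
seen in ≥2 replicates, a homozygote only when consistent across ≥5
replicates, else missing; two competing heterozygote pairs flag a conflict.
Samples typed at <7 loci are excluded. Samples identical at all shared loci
merge; pairs mismatching at 1–2 loci merge only when every mismatch is
dropout-consistent (homozygote vs a heterozygote containing that allele) —
an automated stand-in for manual re-amplification — and are flagged for
review; ≥3 mismatches mean different animals. Merging uses union–find, so
the partition is independent of input order.

PI-sib per locus is 1/4 + (1/2)Σp² + (1/2)(Σp²)² − (1/4)Σp⁴; PI uses the
small-sample unbiased estimator when the sample size is known, and the
plain 2(Σp²)² − Σp⁴ otherwise. Cumulative values multiply across loci
(independence assumption). Expected heterozygosity uses the n/(n−1)
correction on gene copies. The HWE test is the Monte-Carlo exact test
(shuffle gene copies, conditional probability of the genotype array as the
statistic); LD permutes one locus's genotypes across individuals with a
G-statistic; both use the +1 permutation correction, so p is never zero.

## Population structure (`popstruct`)

F_ST is Weir–Cockerham theta from the (a, b, c) variance components summed
over alleles and loci; R_ST is the allele-size analogue
(S̄ − S_W)/S̄ from mean squared size differences, locus-weighted by copy
numbers; pairwise p-values permute individuals between the pair (the
permutation unit is the individual, a choice documented here because the
field tools differ). Phi_PT comes from a squared-distance AMOVA in which
the inter-individual distance is the number of allele differences over
shared loci (pairwise-complete); the three-level AMOVA uses the standard
sums-of-squares decomposition with unequal-n coefficients, truncates
negative components to zero for percentage reporting (raw values retained),
and permutes labels for significance. Rousset linearization d/(1−d) is
applied elementwise before any regression on spatial distance. PCoA is a
double-centering eigendecomposition; negative eigenvalues are reported, not
dropped.

Bottleneck screening: the M-ratio (mean over loci of k/(r+1), r in repeat
units, threshold 0.68 in the literature); the heterozygosity-excess test
simulates equilibrium samples by coalescent-with-mutation conditioned on
the observed allele count per locus (rejection sampling with an
Ewens-initialized, adaptively tuned theta; SMM or TPM mutation), then
applies a one-tailed Wilcoxon signed-rank across loci to the standardized
differences; the mode-shift test bins allele frequencies in 0.05-wide
classes and calls the spectrum L-shaped when the lowest class is modal.
The equilibrium simulation default is 1,000 replicates per locus — enough
for a stable standardized difference at desk scale and configurable upward.

## Assignment and migrants (`assignment`)

**Clustering.** A Gibbs sampler for the admixture model with uncorrelated
allele frequencies: Dirichlet(1) priors on cluster allele frequencies,
Dirichlet(α) on individual membership Q, per-allele-copy origin variables.
α defaults to 0.1; with 11 loci the Q prior is influential, and a small α
(as used in practice for non-admixed data) lets Q concentrate — with α = 1
home-membership saturates near 0.8 even for cleanly separated populations.
The optional locality prior learns a per-locality cluster affinity during
sampling. The data log-probability estimate is the posterior-mean
log-likelihood minus half its variance; the Evanno delta-K statistic
(mean |L(K+1) − 2L(K) + L(K−1)| / sd(L(K))) picks K. Desk-scale defaults
(600 iterations, 200 burn-in) are far below field-tool run lengths; they
are adequate at the simulated divergence levels and configurable. Label
switching across replicate runs is resolved by greedy matching of Q
columns.

**First-generation migrants.** Rannala–Mountain assignment likelihoods:
posterior-predictive genotype probabilities with a Dirichlet(1/k) allele
prior, leave-one-out frequencies for the home population. The statistic is
log10 L_max − log10 L_home, so 2.0 means the home likelihood is 100× below
the best source. Exclusion p-values come from Monte-Carlo resampling:
simulated residents per population drawn from observed frequencies, each
scored with its own alleles removed from the home counts — mirroring the
leave-one-out treatment of real individuals; without this symmetry the
test is anticonservative by about a factor of two. An individual is called
a first-generation migrant only when p < α and the statistic ≥ 2.0.

**Two-generation ancestry.** Each individual has states {resident, gen-1
from j, gen-2 with one immigrant parent from j}. Per locus, gen-1 uses
source-population Hardy–Weinberg probabilities, gen-2 the one-allele-each
mixture. The prior puts 1 − migprior (default migprior = 0.05) on
residency, split evenly over immigrant states. Allele-frequency
uncertainty is integrated by Monte Carlo over Dirichlet posterior draws of
every population's frequencies (default 200 draws) rather than a full
joint MCMC; this "cut" posterior is cheaper and adequate because the
frequency posterior is driven by the labelled sample, not by the focal
individual's state. Recent migration rates aggregate the posteriors:
m[dest←src] is the mean immigrant mass (gen-1 + ½·gen-2) over individuals
sampled in dest, with credible intervals from the frequency draws —
intervals therefore reflect frequency uncertainty given the sample, not
sampling of new individuals. Destinations with n < 5 are excluded. This
aggregate is an acknowledged approximation of the full non-equilibrium
Bayesian migration model, which additionally estimates inbreeding; it
preserves the m-matrix contract (rows sum to one) without a second large
MCMC.

**Parentage.** Per-locus likelihood ratio of "candidate is a parent"
(Mendelian transmission times population frequency for the other allele)
versus "random parent" (Hardy–Weinberg), with a genotyping-error mixture
(1−e)·L_parent + e·L_random so e > 0 keeps LOD finite; LOD is the summed
natural log ratio. Confidence tiers come from simulating offspring and
candidate-parent sets (defaults: 1,000 offspring, 300 candidates, 25% of
parents sampled, 93% loci typed) and choosing the smallest best-candidate
LOD at which 95% (strict) or 80% (relaxed) of assignments are correct.

**Consensus designation.** Migrant requires all of: (i) exclusion p < 0.01
with statistic ≥ 2.0; (ii) migrant probability > 0.5 in both the
admixture-based and ancestry-based analyses; (iii) gen-1 posterior > 0.5
in both. High membership (Q > 0.8) in a single non-home cluster supports
but is not required for designation — individuals can pass (i)–(iii) with
moderate Q. Anyone failing the full rule but showing immigrant evidence
from a single analysis (exclusion p < 0.05, either migrant probability
> 0.5, or non-home Q > 0.8) is Admixed — this covers gen-2-dominant
posteriors, which are deliberately not promoted to Migrant; all others are
Resident. A packaged 17-candidate evidence table exercises this rule
end-to-end (5 Migrant, 12 Admixed).

## Occupancy (`occupancy`)

Covariates are reduced by PCA on the correlation matrix, retaining
components with eigenvalue > 1 and varimax-rotating the retained loadings;
regression scores of the rotated solution feed the occupancy models. The
single-season likelihood is the zero-inflated detection product with logit
links; three detection structures: constant, survey-specific, and linear
in a grid-level abundance index (sign encounter rate). Fitting is L-BFGS-B
with three starts (tolerance 1e-8 on the log-likelihood); standard errors
come from the finite-difference observed information and are inflated by
√Ĉ. Model selection uses AIC; coefficients and per-grid occupancy are
averaged with Akaike weights over models with ΔAIC < 4.

Goodness of fit: parametric bootstrap. The statistic compares observed and
expected detection-history frequencies within survey-count cohorts
(unequal effort makes raw frequencies incomparable across cohorts);
expected counts sum the per-site history probabilities, histories with
expectation < 5 pool into a residual class. Each bootstrap resimulates
histories from the fitted (ψ̂, p̂) and refits before recomputing the
statistic; Ĉ = observed/mean(bootstrap). At desk-scale survey designs Ĉ
has substantial sampling spread for a single dataset (the statistic has
limited degrees of freedom), so calibration is assessed on the mean over
replicate datasets, which sits near 1 on self-simulated data.

Area summaries: naive occupancy is the detected fraction of surveyed
grids; model occupancy is mean ψ̂; occupied habitat weights each grid's
habitat area by ψ̂ (or the detection indicator); increments are reported
in percentage points.

## Connectivity (`connectivity`)

Habitat cells cost 1 − ψ̂ (floored at 10⁻⁶), non-habitat costs a
configurable multiple (default 3.0 — the original cost scheme's exact
values are not public, so this is configuration, logged in provenance),
settlements are impermeable. Least-cost paths: Dijkstra on the 8-connected
lattice, edge weight = mean of the two cell costs × step length (√2 for
diagonals) × cell size; region-to-region distance is the minimum over
member cells; ties resolve by deterministic row-major node order.
Corridors: the path buffered by 1.5 km (cell-center distance), with the
corridor cost recomputed on the graph restricted to the buffer — a cheaper
parallel route inside the corridor can undercut the raw path cost, which
is why recomputation (rather than reusing the path cost) was chosen.
Circuit solves use the 4-connected graph (the standard circuit-tool
default), per-edge conductance = 1/(mean cell cost × cell size), regions
collapsed to supernodes, pairwise effective resistance by sparse Laplacian
solves with one grounded node; disconnected pairs are detected by
connected components and reported as infinite. Current maps assign each
cell half the summed absolute incident edge currents; bottlenecks are
cells above the 95th percentile of current within the corridor mask.

## Spatial models and Mantel tests (`landgen`)

Five spatial matrices — straight-line distance (GGD), log₁₀ GGD, least-cost
path distance (LCPD), corridor distance (LCCD), resistance distance (RD) —
are tested against linearized genetic matrices. The Mantel test correlates
vectorized off-diagonals with a one-tailed (positive association)
permutation null from simultaneous row/column permutation, +1-corrected;
exact enumeration is available for small label sets. Partial Mantel uses
Freedman–Lane residual permutation (regress both matrices on the controls,
permute the response residuals, add back fitted values), chosen over raw
permutation for better type-I control; controls nearly collinear with
either matrix are flagged, and a control that explains a matrix exactly
short-circuits to r = 0. Non-finite cells (disconnected pairs) are dropped
pairwise with an explicit count. The cluster-control matrix (1 between,
0 within genetic clusters) lets isolation-by-distance be separated from
cluster structure.

The end-to-end recovery experiment (`ibr_replicate`) makes circuit
resistance the generating model: matrix movement cost is a strongly
heterogeneous log-normal field (exp(2z), z smoothed noise), so some
inter-patch routes are cheap and others expensive and RD decouples from
straight-line distance; migration decays exponentially in resistance above
its minimum (decay = half the resistance span, most-connected pair at rate
0.10); drift then imprints the resistance pattern on F_ST. Recovering
r(F_ST, RD) > r(F_ST, GGD) in ≥70% of seeded replicates is the pipeline's
headline qualitative check.

## Problem sizes and reproducibility

Default experiment sizes (500-grid occupancy fits, 10–20 replicate
recovery runs, 1,000-genotype exclusion resampling, 100–1,000 bootstrap
and permutation counts, Gibbs runs of a few hundred sweeps) are desk-scale
choices that keep the full test suite and acceptance script in the
low minutes while leaving every count configurable upward. All randomness
flows through explicitly passed seeded generators; the same configuration
reproduces byte-identical artifacts, and the pipeline manifest records
seeds and settings.

## Known limitations

- The admixture sampler fixes α rather than inferring it, uses
  uncorrelated frequencies, and has no linkage model; at very low F_ST
  (< ~0.05) cluster recovery degrades sooner than the full field tool.
- The ancestry posterior integrates frequency uncertainty but not joint
  uncertainty in other individuals' states; credible intervals on
  migration rates are accordingly narrow.
- The exclusion statistic has a point mass at zero (residents whose home
  is the most likely source), so its Monte-Carlo p-values are discrete and
  conservative rather than uniform.
- Ĉ from a single dataset is noisy at small survey designs; use the mean
  over replicates (or larger designs) before correcting standard errors.
- R_ST uses a simple weighted within/total size-variance decomposition;
  with few populations and loci its sampling variance is large, matching
  the general experience that R_ST is the less stable estimator.
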