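# Methods

`rilmap` analyses replicated trait panels measured on a biparental
recombinant inbred line (RIL) population: it estimates heritability and
genotype-by-experiment (G×E) structure, maps QTL by Haley–Knott interval
mapping with permutation-based genome-wide thresholds and stepwise
multi-QTL models, locates QTL hotspots with a sliding-window permutation
statistic, dissects hotspots with additive and all-pairs epistasis ANOVAs,
and maps per-line coefficients of variation (CV) as a stochastic-variation
phenotype.  The package also contains a first-class synthetic-data
generator that emulates the study design the pipeline targets: a rice
*japonica* × *indica* RIL population of 280 lines genotyped at 175 RFLP
markers across 12 chromosomes, grown in two experiments with two randomized
complete blocks each (four replicates per line), measured for a few hundred
positive metabolite-like traits.

## Genetic model and genotype probabilities

A selfed RIL is homozygous, so genotypes take two classes, A (the
*japonica*-type parent, "Lemont") and B (the *indica*-type parent,
"Teqing").  Genetic distance d (cM) converts to a meiotic recombination
fraction with the Haldane map function r = ½(1 − e^(−2d/100)) (Kosambi
available as a configuration switch) and then to the effective RIL
recombination fraction R = 2r/(1 + 2r), the standard map-expansion formula
for a population fixed by repeated selfing.

Genotype probabilities at arbitrary positions condition on the nearest
non-missing flanking markers under a two-state Markov chain whose
off-diagonal transition probability over distance d is R(d):

P(A | g_L, g_R) = P(g_L→A; d_L) · P(A→g_R; d_R) / Σ_s P(g_L→s; d_L) · P(s→g_R; d_R).

This two-flank conditioning (rather than a full multipoint HMM) is exact
when flanking genotypes are observed and is adequate at the marker density
of the target design; it is also easy to verify by brute-force path
enumeration, which the test suite does.  With one informative flank the
chain is run one-sided; a chromosome with no informative marker returns the
unconditional ½ with a warning.  Scan grids include every marker position
plus pseudomarkers inserted so no gap exceeds the step (default 1 cM;
grids in the examples and acceptance runs use 2 cM, which changes nothing
statistically at this marker density and halves the work).

## Haley–Knott scans and permutation thresholds

At each grid position the per-line trait value (a replicate mean) is
regressed on P(A); the LOD is (n/2)·log₁₀(RSS₀/RSS₁) against the
intercept-only null.  LOD is capped at 300 when RSS₁ underflows (noise-free
constructions), preserving ordering without infinities.  With complete
genotypes the probabilities at markers are exactly 0/1, so the scan reduces
to two-group marker regression there; the suite asserts that identity to
1e-8 and LOD invariance under affine trait transformations.

Genome-wide significance uses the permutation null of the maximum LOD:
trait values are shuffled across lines (1000 permutations at α = 0.05 by
convention) and the threshold is the ⌈(1−α)·n_perm⌉-th order statistic of
the null maxima.  Each trait's permutation stream is keyed on the trait's
own values plus the run seed, so results are reproducible and identical
traits give identical output regardless of panel order.

## Multi-QTL models

Stepwise model selection maximizes a penalized LOD: model LOD minus
(main-threshold × n_QTL) minus (interaction penalty × n_interactions).
The main penalty is the trait's permutation threshold; the interaction
penalty defaults to twice that (a deliberately heavy penalty — the
dedicated epistasis module is the instrument for interaction inference) or
can be supplied from a pairwise permutation null.  Forward moves consider
every grid position, interaction terms among selected loci, and optionally
the best marker pair entering jointly with its product term (`pair_search`,
the route by which a purely epistatic pair with no marginal effects can
enter; off by default in panel scans for cost).  Backward elimination then
removes any term whose removal improves the penalized score.  Ties in peak
position break toward the lower cM.  Models are bounded at 10 QTL per
trait by default.

Each retained QTL gets a drop-one LOD (full-model LOD minus the model
without that QTL and its interactions; QTLs below the threshold are pruned
iteratively), a profile LOD along its chromosome with the other QTLs held
fixed, a 1.5-LOD support interval on that profile (the maximal contiguous
run within 1.5 LOD of the peak, clipped at chromosome ends, reported with
flanking marker names), a percent variance explained computed from the
drop-one residual-SS difference over the total SS, and a standardized
additive effect (mean_A − mean_B)/grand-mean with its standard error —
dimensionless, positive when the Lemont allele raises the trait.  Both the
drop-one LOD and the single-QTL scan LOD at the peak are emitted, since
either convention is used for counting QTLs.

## Heritability and G×E

The design is a (near-)balanced randomized complete block layout, so
variance components come from expected mean squares, which are exact and
hand-checkable there; slight imbalance is absorbed through harmonic-mean
cell counts.  Within one experiment: Vg = (MS_line − MS_err)/r and
Vp = Vg + Verr.  Across experiments: Vg = (MS_line − MS_L×E)/(e·b),
Vgxe = (MS_L×E − MS_err)/b, Vexp = (MS_exp − MS_L×E)/(n·b), with negative
estimates truncated at zero.  Combined-scope Vg is the strict among-line
variance (it excludes Vgxe; including it is a configuration option), while
Vp retains the experiment and interaction components — hence combined H²
sits below the within-experiment estimates exactly when those components
are real, the qualitative signature the pipeline is designed to expose.
The replicate-level Type III ANOVA (`fit_gxe_anova`) uses sum-to-zero
contrasts via statsmodels; the vectorized panel version exploits balance.
REML was deliberately not used: on this design EMS is unbiased, exact under
balance, and testable against hand computation.

Per-line CV = sd/mean (sample sd, n−1) over all four replicates (per-
experiment CV is an option); non-positive line means make CV undefined and
missing.  The CV table is emitted in the same long format as raw traits so
the identical scan/hotspot stages consume it unchanged.  Median
normalization divides each sample (line × experiment × block) by its median
across traits (per-trait normalization is a flag); zero-median samples are
flagged and left unscaled.

## Hotspots

The hotspot statistic is the number of QTL peaks within a 10 cM full-width
sliding window evaluated at every grid position.  The null re-places every
detected QTL peak uniformly on the genetic map (preserving the total
count) and records the genome-wide maximum window count; the threshold is
the (1−α) order statistic and a position is a hotspot when its count
strictly exceeds it (so one QTL can never be its own hotspot).  Candidate
peaks from the combined/exp1/exp2 surveys merge by single-linkage
clustering within 10 cM, represented by the highest-count peak's nearest
marker.

Validation refits the whole panel with trait ~ Σ markers + experiment
(markers ±1-coded, missing calls replaced by their conditional expectation
2·P(A)−1, Benjamini–Hochberg FDR within each trait's model) and compares
each marker's significant-trait count against the null obtained by
permuting line labels of the genotypes; a hotspot is valid when its count
strictly exceeds the (1−α) null quantile.  Adding marker × experiment terms
to the same machinery splits each marker's traits into genotype-main-effect
and G×E-dependent counts; a hotspot is "main-effect dominant" when the
former exceeds the latter.  The per-trait standardized allelic effect at a
hotspot marker, with across-trait FDR, is exported as the table behind
network visualizations (positive = Lemont-raising).

## Epistasis

For k hotspot markers the per-trait model is
y ~ Σ M_m + Σ M_m×M_n + experiment + Σ M_m×M_n×experiment on per-(line,
experiment) means with all factors ±1-coded.  Under sum-to-zero coding
every term has 1 df and its Type III SS is b²/(XᵀX)⁻¹_jj, which the package
computes directly (vectorized across traits); statsmodels' Type III ANOVA
is the independent oracle in the tests, and aliased (rank-deficient)
designs are handled through the pseudoinverse with a warning.  P-values are
BH-FDR corrected within each trait's model.

Whether a pair controls more traits than expected by chance is a
permutation question: line labels of the trait matrix are shuffled against
the genotypes (preserving the trait-trait correlation structure, which a
QTL-count null would destroy), per-pair significant-trait counts are
recomputed, and an edge is retained when the observed count strictly
exceeds its own pair's (1−α) null quantile (a pooled null is available).
Experiment dependence of an edge is flagged the same way on the three-way
term.  The per-trait epistatic variance fraction is 100 × ΣSS(pairs) /
ΣSS(all non-intercept terms); on the balanced designs used for checking,
that denominator equals the model SS.  Group comparisons of fractions use
Welch's t-test.  The retained network is exported as SIF plus an
edge-attribute TSV (experiment-dependent edges marked dashed).

## Synthetic data generator

Genotypes are simulated exactly under the genetic model above: each
chromosome is a two-state Markov chain started A/B with probability ½ and
switched between adjacent markers with probability R(d); missing calls are
masked afterwards (2% by default) so trait generation sees the truth.  The
bundled 175-marker/12-chromosome template map follows published rice
genetic-map lengths with uneven spacing and one deliberately large gap on
chromosomes 3 and 9, mirroring the target population's RFLP map.

A trait architecture is y = baseline + Σa_i·x_i + Σw_ij·x_i·x_j +
e·1[exp 2] + Σc_i·x_i·s + ε, with x = ±1 (A/B), s = ∓1 for experiment 1/2,
and ε ~ N(0, (σ·k^{1[B at the variance locus]})²).  The ±1 coding makes
a_i half the A-vs-B class difference; the reporting layer converts to the
standardized allelic-substitution scale.  A variance-QTL multiplies the
residual sd by k for B-carrying lines without moving the line mean — the
generative counterpart of a stochastic-variation locus.  Loci are snapped
to the nearest mapped marker.

The default panel sampler encodes the study conditions, with the variance
budget set by closed-form bookkeeping: 85% of traits carry genetic signal
over 1 + Poisson(3) small additive QTLs with total additive variance
0.9σ²; a quarter of those also carry G×E variance 0.3σ²; experiment main
effects are drawn N(0, 2.5²) and dominate the between-experiment variance;
30% of genetic traits get one product-coded epistatic pair drawn from 15
recurring hotspot-locus pairs; baseline 10 with σ = 1 keeps traits
positive and CV ≈ 0.1.  Under the 2 × 2 replicate structure this puts the
panel median within-experiment H² near 0.5 while the combined-experiment
median drops to roughly 0.2–0.25 — the replication signature the pipeline
is designed to expose.  Half of all QTLs are drawn from 12 shared hotspot
loci (set `hotspot_qtl_frac=0` for independent placement), giving panels
the clustered-QTL structure the hotspot stages look for.  Traits are
Gaussian around a positive baseline rather than log-normal; the generator
makes no attempt to emulate raw chromatography signals, instrument drift or
metabolite identities, so passing tests demonstrate the statistical
machinery, not robustness to real instrument artifacts, skewed abundance
distributions or missing-not-at-random values.

## Numerical and design choices

- LOD cap 300; singular pair-candidate systems regularized with a 1e-9
  ridge during selection only (final fits use QR).
- Order-statistic conventions: thresholds are ⌈(1−α)·n_perm⌉-th ascending
  order statistics; hotspot/validation/enrichment calls require strict
  exceedance; enrichment p-values use the (1 + #{null ≥ obs})/(n_perm + 1)
  convention.
- Ties break toward the lower cM everywhere a position is selected.
- All randomness flows from one seed through named substreams (CRC32 of
  stage names feeding `numpy.random.default_rng` entropy), so changing one
  stage's stream leaves the others untouched and reruns are byte-identical.
- Degenerate inputs: zero-variance traits scan to an all-zero profile;
  all-equal panels give Vg = Vp = 0 with H² defined as 0; fully confounded
  line/experiment designs drop the interaction term with a warning;
  zero-median samples are left unscaled.

## Problem sizes used in the checks

The test suite and the acceptance script run scaled versions of the study:
panels of 200–300 traits on 200–250 lines (the template's 175 markers,
2 cM grid), 1000 permutations for scan thresholds in the headline checks
and 300–500 for the inner permutation loops of simulation-replicated
checks, 20–100 simulation replicates per operating characteristic.  These
sizes were chosen so each statistical property is measured with useful
Monte-Carlo resolution; the defaults in the API remain the study-scale
conventions (1 cM step, 1000 permutations, α = 0.05, FDR 0.05).

## Known limitations

- Two-flank conditioning ignores information from beyond the nearest
  informative markers; with heavy missingness a multipoint HMM would be
  more accurate.
- EMS variance components assume near-balance; badly unbalanced designs
  need REML, which is out of scope.
- The stepwise search is greedy; it can miss configurations a full
  exhaustive two-dimensional scan would find, and the default interaction
  penalty is a convention, not an estimate.
- CV over four replicates is a noisy phenotype; its scans have lower power
  than mean-trait scans at the same architecture, which is intrinsic to
  the design rather than a defect of the implementation.
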