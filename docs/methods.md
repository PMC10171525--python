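# Methods

`brainsig` implements a discovery–validation workflow for *consensus brain
signatures*: data-driven gray-matter (GM) regions maximally associated with a
behavioral outcome, aggregated across many random discovery subsets and
validated for fit replicability against competitor models. This note records
the model, the numerical choices, and what the synthetic benchmark does and
does not establish.

## The model

**Voxelwise association.** For a cohort of n subjects with GM-density volumes
in a common template space, the outcome Y (e.g., an episodic-memory
composite) is regressed at every analysis-mask voxel v:

    Y_i = β0 + β1·GM_i(v) + β2·age_i + β3·gender_i + β4·education_i + ε_i

and the t-statistic of β1 forms the t-map. The implementation residualizes Y
and each GM column against the nuisance design (Frisch–Waugh–Lovell), which
is algebraically identical to the per-voxel full solve but runs as two matrix
products; equality with per-voxel OLS is asserted against an independent
oracle at 1e-8. Voxels with zero GM variance are undefined (NaN), not errors.
Age enters linearly; gender is coded 0/1 (male reference); education is
continuous in years.

**Cluster-size inference.** The t-map is thresholded at t ∈ {3, 5, 7}
(signed, in the expected direction of association by default; negative and
absolute modes exist because inverse-scored outcomes such as everyday-
cognition scales have negative brain–outcome associations). Suprathreshold
voxels are grouped into connected components (26-connectivity by default;
6/18 available) and a component is retained only if its size reaches the
empirical 95th percentile (inclusive) of the max-cluster-size distribution
under permutation. Permutations follow the Freedman–Lane scheme: residuals
of Y under the nuisance-only model are shuffled and added back to the
nuisance fit, preserving the covariate structure; a raw shuffle is available
for comparison. The identity permutation is included as the first member of
the null, the convention that keeps the retention rule approximately exact.
Each t-level gets its own null (2000 iterations at production scale).
Empirical check: over 200 simulated no-effect cohorts the family-wise error
of the full procedure is 5–7% at nominal 5% (binomial SD ≈ 1.5%).

**Consensus aggregation.** Discovery is repeated over K random subsets of
the discovery cohort (defaults K=40, size 400, drawn uniformly without
replacement within each subset, independently across subsets — mean pairwise
overlap is therefore the hypergeometric size²/N). Per t-level, subset masks
are summed into an overlap frequency map and the consensus mask keeps voxels
present in at least ⌈0.70·K⌉ subsets (28 of 40). One master seed spawns
per-subset sub-seeds, so subsets can be recomputed independently with
identical results.

**Signature variable.** For any target set, mean GM within each consensus
mask gives three per-subject predictors; the signature variable S is the
vector of fitted values from

    Y = b0 + b1·TsROI1 + b2·TsROI2 + b3·TsROI3.

S is refit within each target set by default (the frozen-coefficients
alternative — fit once, apply elsewhere — is `SignatureModel.predict`).
Because the three masks are nested in practice, their means can be nearly
collinear; an ill-conditioned design (condition number > 1e10) falls back to
a pseudo-inverse solve and is flagged. Empty consensus masks (possible at
small discovery sizes) drop their term with a warning.

**Evaluation.** Model fit is adjusted R² = 1 − (1−R²)(n−1)/(n−p−1), from
the outcome model Y ~ S + age + gender + education. Replicability: two
signature models are refit in each of many random validation subsets
(defaults 50 subsets of 200) and their paired adjusted R² compared by
Pearson correlation and Bland–Altman analysis (bias, 1.96·SD limits of
agreement, t-based CI of bias — the CI type is our choice and is labeled).
Superiority: subjects are resampled with replacement (default 10,000
iterations), both models refit per resample, and percentile CIs of
adj R²_S − adj R²_M formed at the 80/90/95/99% levels; an interval entirely
above zero flags superiority at that level. BCa intervals are available as
an option. Competitors: demographics-only, single atlas-ROI, four atlas ROIs
jointly ("FourROIs"), and covariate-dropped variants. Diagnosis interaction:
Y ~ demographics + S + diagnosis + S×diagnosis with dummy-coded diagnosis;
blocks are tested by partial F (main effect in the model without
interactions, interaction in the full model); no multiplicity correction is
applied across the model battery.

**Spatial similarity.** Dice uses the standard 2|A∩B|/(|A|+|B|) by default;
the union-denominator variant 2|A∩B|/|A∪B| is provided (mode "union") but
note it reaches 2 for identical masks. Mask *sets* are compared through a
coded volume assigning each voxel the highest t-level containing it
(0/3/5/7), scored by η² = 1 − Σ[(aᵢ−mᵢ)²+(bᵢ−mᵢ)²]/Σ[(aᵢ−M̄)²+(bᵢ−M̄)²];
η² is 1 for identical maps and sensitive to local and global magnitude
differences. Atlas overlap tables report |mask ∩ region|/|region| per label,
sorted descending.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline's claims are checked. A subject's volume is

    template + Σ_r effect_size_r · latent_i · 1[region_r] + smoothed noise,

with the template a smooth positive field (baseline ≈ 1), the latent trait
standard normal, regions axis-aligned boxes or spheres, and noise white
Gaussian smoothed by a σ=1-voxel kernel (rescaled by the kernel L2 norm so
the stated SD holds after smoothing — spatial autocorrelation is what makes
cluster-size nulls nontrivial). The outcome is

    outcome_sign · loading · latent_i + γ_age·age_i + γ_edu·edu_i + ε_i,

with outcome_sign = −1 emulating inverse-scored instruments. Demographics:
age ~ U[55, 90] years, education ~ U[8, 20] years, gender ~ Bernoulli(½).
Diagnosis (CN/MCI/Dementia) is assigned by configurable outcome-severity
quantiles (tertiles by default). Defaults — effect 0.05 GM units per SD of
latent trait, noise SD 0.06, loading 0.6, outcome noise SD 0.5 — give
planted-region t-values near 12 at n=400, i.e., a clearly detectable but
spatially confined substrate.

Not emulated: scanner/site effects, registration error, subject-specific
anatomy, longitudinal change, non-box substrates. Passing recovery tests
therefore shows the *algorithm* is correct and well calibrated under its own
assumptions, not that real cohorts at these sizes would yield Dice-1
recovery; real-data fit levels (adjusted R² and spatial similarity values)
depend on the cohort and are not reproduced by the benchmark.

## Problem sizes used by the checked studies

The test suite runs the full pipeline at reduced scale, chosen so each study
keeps its statistical meaning: FWER calibration uses 200 null cohorts of
n=60 on a 16³ grid with 500 permutations; planted-effect recovery uses two
discovery cohorts of n=400 on a 24³ grid (8 subsets of 300, 200 permutations
per t-level) plus an independent validation cohort (25 subsets of 150);
model-ordering uses 3 replicates with 6 subsets and 300 bootstrap
iterations. Production defaults (40/400, 2000 permutations, 50/200, 10,000
bootstrap) remain the package defaults and are exercised verbatim by the
configuration layer.

## Numerical choices and degenerate inputs

- Empirical quantile for cluster retention: smallest size s with at least
  (1−α)·n_perm null values ≤ s; retention is inclusive (≥).
- Consensus count threshold uses ceiling (≥ 70% inclusive: 28/40).
- Cluster ordering is deterministic (size descending, ties by smallest
  linear voxel index); labeling is verified against a flood-fill oracle.
- Zero-variance GM voxels: undefined, skipped by thresholding. Constant
  covariates: error naming the column. Rank-deficient bootstrap resamples:
  redrawn and counted.
- Volumes are aligned iff shape, voxel sizes, and space tag match; no
  resampling is performed anywhere.
- All randomness flows from `numpy.random.SeedSequence` spawns of one master
  seed; every artifact directory carries a provenance JSON with the full
  config, its hash, and the seed, and re-runs are byte-identical.

## Known limitations

- Consensus masks across t-levels are used as-is (overlapping), so the
  signature design is often ill-conditioned; the flagged pseudo-inverse path
  makes this safe but the individual b-coefficients are then not
  interpretable (S, their fitted combination, is).
- The permutation engine assumes exchangeable residuals under the nuisance
  model; heteroscedastic or family-structured cohorts would need a different
  scheme.
- η² between mask sets depends on the 0/3/5/7 coding convention; other
  codings would shift absolute values (comparisons within one convention are
  unaffected).
- The CLI's `consensus` subcommand is an alias of `discover`: consensus
  construction is the final step of the discovery stage.
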