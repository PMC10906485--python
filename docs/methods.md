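# Methods

## Phylogenetic covariance

A trait evolving by Brownian motion with rate σ² along a rooted tree
yields tip values distributed MVN(μ·1, σ²·C), with `C[i,j]` the branch
length shared by the root-to-tip paths of tips *i* and *j* and `C[i,i]`
the depth of tip *i*. `Tree.vcv()` builds C by most-recent-common-
ancestor depths; a brute-force edge-set-intersection oracle verifies it
in the tests. Depths are measured from the origin above any root edge,
so pruning a tree and then building C gives exactly the submatrix of the
full tree's C (after pruning, the seed edge absorbs whatever shared
root path the collapsed nodes carried).

Trees need not be ultrametric; polytomies and zero-length internal
branches are accepted. Tip labels are matched with spaces and
underscores interchangeable (Newick dialects disagree; study phylogenies
typically use underscored binomials), case-sensitive otherwise.

Pagel's λ multiplies the off-diagonal of C; λ = 0 is the independence
(star-tree) limit, λ = 1 full Brownian covariance.

## PGLS

`fit_gls` whitens the design and response by the inverse Cholesky factor
of C and solves the resulting OLS problem, which is algebraically
`beta = (X'C⁻¹X)⁻¹X'C⁻¹y`. Reported quantities:

- `sigma2 = RSS_C / (n − p)` (unbiased scale), with standard errors from
  `diag((X'C⁻¹X)⁻¹)·sigma2` and two-sided t tests on n − p df.
- `loglik` is the *maximized* Gaussian likelihood (ML scale, RSS/n), so
  −2lnL and AIC are comparable across fixed-effect structures;
  `AIC = −2lnL + 2k` with `k = p + 1` (coefficients plus σ²). REML is
  deliberately not used anywhere, because λ estimates and model AICs are
  compared across models with different fixed effects.
- `r_squared = 1 − RSS_C/TSS_C`, both quadratic forms in the C metric,
  with TSS_C from the GLS intercept-only fit under the same C. This is
  the natural GLS generalization of R² and lies in [0, 1] for intercept
  models; it is recorded here because published PGLS R² values rarely
  state their definition.
- Cook's distances computed on the whitened model with the standard OLS
  influence formula; a leave-one-out refit oracle verifies them.

Degrees of freedom are reported as n − p; because the field sometimes
prints t subscripts equal to n, the report emits both `df_residual` and
`n_obs` so either convention can be checked.

Numerics: Cholesky of C, falling back to eigenvalue clipping at 1e-10 of
the largest eigenvalue when near-singular C (e.g. zero-length terminal
branches) defeats the factorization. Rank-deficient designs raise
rather than pseudo-solve.

## Pagel's λ estimation and its LRT

λ̂ maximizes the intercept-only ML likelihood over the λ-transformed C
on [0, 1] (bounded scalar minimization, tolerance 1e-8, endpoints
checked). Significance against λ = 0 uses the likelihood-ratio
statistic with the plain χ²₁ upper tail by default; a
`boundary_mixture` flag switches to the 50:50 point-mass/χ²₁ mixture
appropriate for a boundary null. The implementation agrees with
phytools' `phylosig` to ≈1e-5 in λ̂ and log-likelihoods on shared
datasets (frozen cross-check in the tests).

A calibration caveat the tests document deliberately: on 200-tip
pure-birth trees the boundary LRT is strongly conservative — under
λ = 0 the estimate sits exactly at zero far more than half the time, so
even the mixture p-value rejects at roughly 0.01–0.02 rather than the
nominal 0.05 (the phytools implementation behaves identically). The
acceptance test asserting a [0.03, 0.07] type-I band therefore fails,
and is expected to: it records the measured size of the test rather
than forcing it. λ̂ point recovery is unaffected (mean bias < 0.05 at
generating λ ∈ {0, 0.5, 1}).

## Phylogenetic ANCOVA

`ancova_interaction` fits response ~ continuous × factor under C with
treatment coding (reference = first level alphabetically, for
determinism). The interaction p-value is the t test on the interaction
coefficient for two-level factors, and a likelihood-ratio test against
the no-interaction model (χ² with L−1 df) otherwise. Its practical use
here is testing whether behaviorally measured and anatomically (RGC
density) measured acuity share an eye-size slope before pooling them.

## Residual cascade

Stage 1 regresses log eye size on log body mass under C; residuals are
*relative eye size* (positive = larger eyes than the allometric
expectation — the direction follows from regressing eye size *on* mass,
which is the only reading consistent with that interpretation). Stage 2
regresses log acuity on relative eye size under C; residuals are
*residual acuity*. Exactly collinear stage-1 input (zero noise) makes
the stage-2 design rank-deficient and raises.

## Model selection

All 2^m subsets of the candidate predictors, including the
intercept-only model, are fitted under a common C and ranked by AIC
(AICc available by flag but not default). Categorical predictors enter
as whole treatment-coded blocks — a subset either includes the entire
factor or none of it, matching how ecological classifications are
treated as single predictors. Akaike weights are
`exp(−Δ_i/2)` normalized over the set. The collinearity pre-screen
scores numeric pairs by Pearson r, categorical pairs by Cramér's V and
mixed pairs by the correlation ratio η (the measure used is recorded
with each flag, since mixed-type association has no single convention);
pairs exceeding the threshold (default 0.7, strict) are flagged, and
constant columns are flagged as "undefined" rather than scored.

## Phylogenetic ANOVA

The omnibus F is the ordinary one-way ANOVA statistic on the raw data.
Its null distribution is built by re-simulating the trait under
Brownian motion on the study tree — rate and mean set to their ML
estimates from the observed trait — while keeping the observed group
labels fixed (the Garland-style construction), and recomputing F for
each of `n_sims` simulated traits. The tail probability uses the +1
correction, `(1 + #{F_sim ≥ F_obs}) / (1 + n_sims)`, so it is never
exactly zero, and is bit-for-bit reproducible given the seed. Because F
is location/scale-invariant, the simulated statistics are exchangeable
with the observed one under the null, making the test exact up to
Monte Carlo error; the acceptance suite measures its size at ≈0.05.

Post hoc pairwise contrasts use t statistics with pooled within-group
variance; their raw p-values come from the same simulation null (tail
frequency of |t_sim| ≥ |t_obs|), for consistency with the omnibus test,
with classical t-distribution p-values reported alongside. Holm's
step-down correction is applied across the L(L−1)/2 comparisons.
Estimated marginal means are the coefficients of a cell-means GLS fit
under C; ordinary (identity-covariance) means are emitted as well,
since published tables rarely state which was used.

## Ecological classifiers

All classifiers are pure functions that fail loudly on unclassifiable
input rather than defaulting, because published assignments of this
kind are manual.

- **Habitat**: stratum percentages are summed into complex (understory
  + mid-high vegetation), open (aerial + open water) and
  horizon-dominated (ground + water surface + canopy); the class whose
  sum strictly exceeds 70% wins (at most one can), otherwise
  *generalist*. The boundary is strict because the defining phrase is
  "greater than 70%": exactly 70 is a generalist.
- **Light level**: nocturnality forces *low* regardless of habitat
  (owls, deep-foraging seabirds). Otherwise fixed keyword tables vote:
  low {forest understory, mangrove, dense shrubland, heathland, dense
  habitat}, high {desert, grassland, savannah, farmland, steppe,
  meadow, pelagic ocean, open antarctic island, flat beach, dune,
  mudflat}, medium {forest edge, secondary forest, scrub forest,
  semi-open}; ties go to medium.
- **Diet**: raw scores (EltonTraits-style 10 categories, editable
  mapping) aggregate to plants / invertebrates / vertebrates-and-
  scavenged; the category reaching ≥50% wins, none → omnivore, and a
  50/50 tie is an omnivore (only the omnivore side of the boundary is
  defined by the source rule, "less than 50% for all").
- **Prey mobility**: mobile = live vertebrates + invertebrates,
  immobile = plant matter + scavenged prey; an exact tie raises for a
  manual call rather than guessing.
- **Foraging mode**: *far* if the species' primary (first-listed)
  maneuver is a distance maneuver (aerial chase, pursuit diving,
  scavenging, sallying), else *near* (gleaning, pecking, dabbling,
  kicking/scratching, probing). "Primary = first listed" is an explicit
  convention — the source classification is per species with no stated
  weighting — and is overridable by reordering the input.

Acuity units convert to cycles per degree as: MAR arcmin → 30/value,
MAR degrees → 0.5/value (one grating cycle spans two MARs; 60 arcmin
per degree), cycles/radian → value·π/180. Record selection keeps
RGC-density estimates over behavioral ones, the most recent study
within the preferred method, and breaks remaining ties by the highest
reported acuity.

## Synthetic data generator

The generator emulates the study conditions end to end and is the basis
of every recovery and calibration test. Defaults (chosen once):

| parameter | default | rationale |
|---|---|---|
| n_tips | 94 | the study's species count |
| birth_rate | 1.0 | time unit is arbitrary; sets tree depth ≈ H_94 − 1 ≈ 3.6 |
| sigma2_mass | 1.0 | log-gram tip SD ≈ 1.9, a realistic avian mass spread |
| allometric slope (eye~mass) | 0.23 | the reported avian allometry |
| acuity slope (acuity~eye) | 0.81 | the reported acuity–eye-size slope |
| eye noise rate | 0.005 | gives eye~mass R² ≈ 0.93 at default depth |
| acuity noise rate | 0.03 | gives acuity~eye R² ≈ 0.56 at default depth |
| λ_gen | 1.0 | fully Brownian residuals |
| RGC fraction | 0.75 | ≈ the study's 71:20 RGC:behavioral split |

Ecological labels are assigned per variable either iid or (default)
clade-clustered by thresholding an auxiliary Brownian trait at its
empirical quantiles — the phylogenetically non-random membership that
motivates phylogenetic ANOVA — with configurable additive effects on
log acuity. Labels are then materialized as raw stratum percentages,
diet scores, habitat keywords and maneuver lists that the classifiers
provably invert (a test checks classification recovers every generating
label). Because diet class and prey mobility derive from the same raw
scores, plant-eaters are necessarily immobile-prey foragers and
insectivores mobile-prey foragers; the vertebrate/scavenger and
omnivore classes realize either mobility. This mirrors real trait
databases and means the two variables are correlated by construction
(Cramér's V ≈ 0.7, which the collinearity screen duly flags).

One RNG stream drives the whole dataset, so a fixed seed reproduces
tree, table and true-values ledger byte for byte.

What the generator does *not* emulate: measurement error in acuity or
eye size, non-Brownian (e.g. Ornstein–Uhlenbeck) trait dynamics,
extinction (trees are pure-birth), missing data patterns, or
correlated selection of ecological states along the tree. Passing
recovery tests therefore show the estimators are correct under the
model's own assumptions, not that the assumptions hold for real data.

## Pipeline

Stages, in order: record selection (unit conversion at ingest) →
ecological classification → drop species missing eye size or body mass
→ optional method subset (all / rgc_only / behavior_only) → prune tree
(species absent from the tree abort with the list of names) → natural-
log transforms (base configurable and recorded) → Pagel's λ on log
acuity → acuity ~ eye size PGLS with single-pass Cook's-distance
exclusion (default `4/n`; `topk:K` reproduces a named exclusion set)
and refit on the re-pruned tree → collinearity screen → all-subsets
model tables (64 models; 32 with eye size forced absent) → residual
cascade → phylogenetic ANOVA + Holm post hocs + marginal means for
each of the five ecological variables crossed with log acuity, relative
eye size and residual acuity.

Species conservation holds exactly: input = analyzed + missing-data
drops + subset exclusions + outlier exclusions. ANOVA seeds are derived
deterministically from the config seed per variable × response combo.
If a resampled dataset leaves an ecological level with fewer than two
members, that variable × response cell is recorded under
`skipped_variables` with the reason instead of aborting the run — the
underlying operation itself still raises when called directly. Outlier
exclusion is single-pass by design (fit once, exclude, refit once); an
iterative rule would change the exclusion set and is intentionally not
offered.

The report carries full provenance (config snapshot and hash, seed,
package version); re-running with the same config reproduces every
output file byte for byte.

## Problem sizes used in the checks

Recovery and calibration studies run at: λ recovery 100 replicates per
generating value on 200-tip trees, with 300 replicates for the LRT size;
slope recovery and CI coverage 500 replicate 94-species studies; ANOVA
calibration 500 datasets × 500 simulations at 50 tips; outlier
uniqueness 100 replicates at n = 60 with an evenly spaced predictor,
noise SD 0.3 and a 10-response-SD displacement (with heavy-tailed
leverage in the predictor, a displaced point can drag a clean
high-leverage point over the 4/n cutoff — "swamping" — so the
uniqueness property is stated for the bounded-leverage, high-signal
regime that matches tight allometries). The acceptance script re-runs
scaled versions of the same studies and reports every number it
computes.

## Known limitations

- Brownian motion only: no OU or early-burst covariance, no measurement
  error model, no mixed models.
- The λ profile likelihood is intercept-only (signal in a single
  trait); λ is not jointly estimated inside regressions.
- Post hoc simulation p-values inherit Monte Carlo granularity 1/(n_sims+1).
- The boundary LRT for λ is conservative (see above); report effect
  sizes (λ̂ itself) rather than leaning on its p-value near λ = 0.
- Classifier keyword tables are fixed vocabularies; inputs outside them
  must be mapped by the user beforehand.
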