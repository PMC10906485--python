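# birdacuity

Phylogenetically controlled comparative analysis of avian visual acuity:
how the finest spatial detail a bird can resolve (in cycles per degree,
cpd) relates to eye size, body mass and ecology, while accounting for
the non-independence of related species.

The package is aimed at visual ecologists and comparative biologists who
have (a) a rooted phylogeny with branch lengths in Newick format and (b)
a per-species trait table (acuity with its unit and measurement method,
eye axial length, body mass, foraging-stratum and diet percentages,
habitat keywords, foraging maneuvers). It also ships a synthetic-data
generator that emulates the full statistical structure of such a study,
so every method can be exercised and validated without any external
data.

## The model

Under Brownian trait evolution on a rooted tree, tip values are
multivariate normal with covariance **C**, where `C[i,j]` is the branch
length shared by the root-to-tip paths of species *i* and *j*.
Regressions are fitted by phylogenetic generalized least squares (PGLS):

    beta = (X' C^-1 X)^-1 X' C^-1 y,    sigma^2 = RSS_C / (n - p)

Phylogenetic signal in a trait is measured by Pagel's λ ∈ [0, 1], which
scales the off-diagonal of **C** (0 = star-like independence, 1 = full
Brownian covariance) and is estimated by maximum likelihood with a
likelihood-ratio test against λ = 0.

On top of this core the package implements:

- a **residual cascade**: *relative eye size* = residuals of log eye
  size ~ log body mass (PGLS); *residual acuity* = residuals of log
  acuity ~ relative eye size (PGLS) — acuity beyond what eye investment
  predicts;
- **all-subsets AIC model selection** over eye size + five ecological
  predictors (2⁶ = 64 PGLS models) with Akaike weights
  `w_i = exp(-Δ_i/2) / Σ_j exp(-Δ_j/2)`, plus a |assoc| > 0.7
  collinearity pre-screen;
- **phylogenetic ANOVA** with a Brownian simulation null (trait
  re-simulated on the tree with group labels fixed), Holm–Bonferroni
  post hoc contrasts and estimated marginal means;
- **Cook's-distance outlier exclusion** on the whitened model
  (`4/n` rule, or `topk:K` to reproduce a named exclusion set);
- deterministic **ecological classifiers**: habitat spatial complexity
  (strict >70% rule), habitat light level (keyword tables with a
  nocturnality override), dominant diet (≥50% rule), prey mobility and
  far/near foraging mode.

## Worked example

```sh
python examples/05_full_pipeline.py
```

```
species analyzed: 88 of 94 (6 Cook's-distance outliers excluded)
Pagel's lambda on log acuity: 1.000 (p = 1.5e-43)
acuity ~ eye size slope: 0.748 +/- 0.076 (R^2 = 0.53)
eye size ~ body mass slope: 0.237 +/- 0.008
best AIC model: foraging_mode + log_eye_size (weight 0.26)
```

This simulates a 94-species study under the package's default
conditions (allometric slope 0.23 of log eye size on log mass, acuity
slope 0.81 on log eye size, fully Brownian residuals) and recovers
those quantities by the full pipeline: strong phylogenetic signal in
acuity, an acuity–eye-size slope near the generating 0.81 with roughly
half the variance explained, an eye–mass allometry near 0.23, and an
AIC ranking whose weight concentrates on models containing eye size.
The other `examples/` scripts demonstrate each capability (covariance
construction, PGLS + λ, model selection, phylogenetic ANOVA) in
isolation.

The same pipeline is available from the shell:

```sh
birdacuity simulate --n-tips 94 --seed 42 --out data/
birdacuity run --tree data/tree.nwk --traits data/traits.csv \
               --out results/ --seed 43
birdacuity classify --traits data/traits.csv
birdacuity anova --tree data/tree.nwk --data groups.csv --seed 7
```

`run` writes `report.json`, tidy CSVs (model table, Holm-corrected
contrast table, per-species classifications and residuals), the pruned
Newick tree and a log file; everything is byte-stable given the seed.

## Layout

- `src/birdacuity/phylo.py` — Newick trees, pruning, Brownian covariance, λ transform
- `src/birdacuity/inference.py` — PGLS, Cook's distance, Pagel's λ, ANCOVA, residual cascade
- `src/birdacuity/model_select.py` — all-subsets AIC, Akaike weights, collinearity screen
- `src/birdacuity/group_compare.py` — phylogenetic ANOVA, Holm correction, marginal means
- `src/birdacuity/ecology.py` — unit conversion, record selection, classifiers
- `src/birdacuity/synthetic.py` — Yule trees, Brownian traits, full dataset generator
- `src/birdacuity/pipeline.py`, `cli.py` — orchestration, reporting, command line
- `docs/methods.md` — models, assumptions, parameter choices, limitations
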