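# Methods

This note records the statistical models implemented in `scfa_micromap`,
the numerical conventions they rely on, the design choices that were
genuinely open, and what the synthetic validation does and does not show.

## Partial canonical correspondence analysis

CCA ordinates a nonnegative sample-by-taxon table under the chi-square
metric, constrained to explanatory variables. We use the weighted-SVD
formulation: with proportions `P = Y / Σ Y`, row weights `r`, column
weights `c`, the standardized residual matrix is
`Q_ij = (P_ij − r_i c_j) / √(r_i c_j)` and total inertia `‖Q‖²`. Condition
and constraint columns are r-weighted centered, standardized to unit
weighted variance, and scaled by `√r`; `Q` and the constraints are
residualized on the conditions (removed inertia = conditional inertia);
the projection of the residual `Q` onto the residual constraint span is
decomposed by SVD, with `λ_k = s_k²`. Scores follow the ecology
conventions: species scores `V/√c` times `s_k` (species-focused scaling,
numerically identical to vegan's `scaling = 2` species scores, verified in
the test suite against `vegan::cca` through `Rscript`), site scores as
linear combinations of constraints, biplot arrows as r-weighted
correlations of each constraint with the site scores stretched by `s_k`
per axis. Axis signs are fixed by orienting each axis so its dominant
constraint is positive.

Degenerate designs are handled explicitly: collinear constraints raise an
error naming the offending columns, while constraint span absorbed by the
conditions is legitimately dropped (conditioning on a copy of the single
constraint yields zero constrained inertia and zero axes).

**Permutation test.** The model pseudo-F is
`(constrained/q) / (residual/(n − q − z − 1))` with `q` constrained axes
and `z` condition columns. The null is generated by reduced-model
(Freedman–Lane) permutation: the conditions-only fit of `Q` stays attached
to the samples, its residuals are row-permuted and re-residualized, and F
is recomputed against the fixed constraint span, `p = (1 + #{F* ≥ F}) /
(1 + n_perm)` with 999 permutations by default. Row weights are held fixed
under permutation (they are uniform for closed relative tables). The
conditioning variable thereby keeps its confounding role under the null,
which is what makes the transit adjustment honest.

## Projection-score ranking

In the plane of the first two constrained axes (the printed biplot), each
taxon's species-score vector `v` is projected onto the unit vector `u` of
an SCFA arrow. The angle is measured to the arrow's axis *line*
(`θ = arccos(|⟨v,u⟩| / ‖v‖)`), so anti-parallel taxa — negative
associations — are retained with negative scores. Retention requires
`θ ≤ 30°` (a 60° total cone) and `|⟨v,u⟩| ≥ 0.5`; survivors are ranked by
`|score|`, ties broken lexicographically. With a single-constraint model
there is one constrained axis; the cone degenerates to a sign and only the
0.5 threshold applies. The 0.5 cutoff lives on the species-focused score
scale described above; it is configurable because the scale depends on the
chosen scaling convention.

Two geometric facts matter for study design. First, with k constraints
there are k constrained axes but the ranking plane holds only the first
two, so the axis of the weakest constraint in a joint model can fall
outside the plane entirely; per-SCFA single-constraint models avoid this
and are the mode used by the validation experiments. Second, the score of
a taxon scales as `√(λ/c_j)` — rarer taxa get larger scores for the same
share of a constrained axis — which is inherent to chi-square ordination.

## PERMANOVA

Distances are Gower-centered (`G = −½ J D² J`); sums of squares are traces
of projections of `G`, computed in principal-coordinate space with
negative eigenvalue mass carried with its sign (no correction). Terms are
sequential — covariates first, group last — so the group pseudo-F is the
adjusted test. Permutation uses Freedman–Lane on the reduced (covariate)
model, which reduces to free sample permutation when no covariates are
present. The implementation agrees with `scikit-bio`'s PERMANOVA to 1e-10
on the unadjusted case and with a textbook within/between partition on
balanced one-way designs.

## Bayesian-network consensus

Structures over (ALR taxa, SCFAs, transit) are learned by greedy hill
climbing on the decomposable Gaussian BIC score,
`Σ_i [ −n/2 (ln 2πσ̂²_i + 1) − (|Pa_i| + 2)/2 · ln n ]`, from the empty
graph, with single-edge additions/deletions/reversals and lexicographic
tie-breaking for determinism. Local scores come from Schur complements of
the empirical covariance matrix, which makes bootstrap ensembles cheap.
The consensus keeps edges whose direction-blind bootstrap frequency
reaches 50% (500 resamples by default), orients them by majority
direction, annotates each with the sign of the corresponding partial
correlation (an annotation only, never a filter), and breaks any directed
cycle by dropping the cycle's lowest-frequency edge.

Two practical notes. ALR vectors share the reference part's noise, so all
pairs of ALR taxa are positively correlated by construction; on data sets
with many weakly-coupled taxa this yields dense learned graphs. The
pipeline therefore bounds the network's taxon set (default: the 30 taxa
with the largest species-score norm in the ordination) and caps parent
sets at 5 by default — both configurable. These bounds are about
statistical sanity at n ≈ 60 as much as speed.

## Group statistics

Kruskal–Wallis uses the tie-corrected H; Dunn's pairwise z uses mean ranks
with the standard tie term, Bonferroni-corrected by the number of pairs
actually tested. Constant traits short-circuit to a flagged degenerate
result (p = 1). Per-taxon group contrasts are OLS on the ALR scale with
group dummies plus covariates; no multiplicity correction is applied by
default (Bonferroni/Benjamini-Hochberg available as flags), matching the
hypothesis-generating framing of this kind of cohort analysis. Zero-
residual fits are flagged degenerate rather than reporting spurious
t statistics. GMM association restricts a KO table to module members and
runs the same models per KO, grouped per module.

## Synthetic cohort generator

The generator is the package's study-conditions encoding, not a fixture:

* **Groups and traits.** HV/IBS-C/IBS-D of 17/15/26 samples; transit
  log-normal with medians 1.4/1.5/0.9 days (log-sd 0.45); SCFA intercepts
  9.5/2.4/2.7 µg/mg; stool bile-acid totals log-normal with medians
  342/190/607 µmol/48h and a BAM flag thresholded at 1000 µmol/48h; age,
  sex, BMI and diet covariates at plausible adult scales.
* **Composition.** Latent log-abundance = skeleton (N(0, 1.0)) + δ·transit
  + N(0, σ), row-softmaxed onto the simplex; 120 taxa. Background
  dispersion σ = 0.35; twelve δ-taxa with slopes ±0.8 per day carry the
  transit confounding. An optional multinomial count layer simulates
  finite sequencing depth.
* **Drivers.** Six planted drivers by default (one ± pair per SCFA) with
  loadings β = ±0.5 (acetate) and ±0.3 (butyrate/propionate) per unit ALR,
  acting through the taxon's log-abundance noise net of transit. Driver
  taxa get dispersion 2.4 and a pinned skeleton level of −1.2 — the
  bloom-like variability of fermenters is what gives them the chi-square
  inertia a real signal carries in an ordination.
* **SCFA.** intercept + Σ β·(centered driver ALR) + γ·transit + N(0, 0.25),
  truncated at zero by resampling the noise (no point mass at zero).
  Transit slopes γ = (−1.5, −0.3, −0.3) µg/mg per day: faster transit,
  higher stool SCFA.

Effect sizes are not identifiable from published summary tables, so they
were chosen once, on the criterion that the planted structure should be
recoverable by a correctly implemented pipeline at n = 60/group while the
no-driver null stays calibrated, and then frozen. Two interactions
discovered while fixing these values are worth recording. (i) Zero-
truncation combined with steep transit slopes makes E[SCFA | transit]
nonlinear exactly at high-leverage extreme-transit samples; linear
conditioning cannot remove that component, and the permutation test then
anti-conserves badly. The default slopes are gentle enough that truncation
is rare and calibration holds (null rejection ≈ 0.05 at α = 0.05).
(ii) The acetate:butyrate ratio is a nonlinear function of two transit-
dependent quantities; including it as a constraint inflates the
conditioned test for the same reason. The ratio therefore stays in the
descriptive four-panel ranking set but out of the calibration-sensitive
analyses, which use the three concentrations.

**What the synthetic validation shows — and does not.** Passing tests
demonstrate that the algebra is right (oracle equivalence), that the
permutation schemes are calibrated under a confounded null of the stated
form, and that planted log-linear microbe–SCFA couplings of the stated
size are recovered with correct signs. Real stool metagenomes add
features the generator does not emulate: sequencing zeros far in excess
of the logistic-normal tail, taxon–taxon ecological interactions,
nonlinear transit physiology, batch structure, and compositional effects
of unobserved total load. Recovery here is therefore a correctness check
on the machinery, not a power guarantee for any real cohort.

## Numerical conventions

Rank decisions use singular-value thresholds of 1e-9 relative to the
column scale with an absolute floor, so spans that are numerically zero
(e.g. constraints absorbed by conditions) drop out instead of producing
garbage axes. Relative-abundance rows must close to 1 within 1e-9; ALR
pseudocounts default to half the smallest nonzero abundance and the ALR
reference defaults to the feature with the highest minimum abundance.
Permutation p-values use the add-one convention and are bounded below by
`1/(n_perm + 1)`. All randomness flows through `numpy.random.default_rng`
seeds; the pipeline fans a single seed out to fixed per-stage offsets so
toggling one stage does not shift another's stream.

## Validation problem sizes

The shipped validation runs use: 50 random 10×6 tables for the ordination
oracle, 100 instances for inertia conservation, 200 simulated cohorts
(n = 60) at 199 permutations for type-I error and 100 for power, 50 seeds
at n = 60/group for driver recovery, 25 seeds × 100 bootstraps for the
chain-recovery experiment, and 50 seeds × 25 bootstraps (15-node networks)
for the ranking/network concordance — sizes chosen to give stable Monte-
Carlo estimates at interactive runtimes on a single CPU.

## Known limitations

The pCCA permutation holds row weights fixed (exact for closed tables,
approximate for raw counts). The Freedman–Lane scheme assumes the
condition enters linearly; strongly nonlinear confounding is only
partially removed, as the truncation study above illustrates. The BN
consensus assumes joint Gaussianity of ALR values and metabolites and
cannot orient score-equivalent edges (ties are flagged undirected).
Within-module alternative-path logic of the original gut-metabolic-module
framework is not implemented; modules are flat KO sets.
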