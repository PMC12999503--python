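# Methods

This note records the models and procedures enantiokit implements, the
defaults it ships, and what its synthetic benchmarks do and do not
demonstrate.

## Selectivity thermodynamics

Enantioselectivity is modelled through the free-energy gap between the two
diastereomeric stereocontrolling transition states,

    ΔΔG‡ = R·T·ln((1 + ee)/(1 − ee)),   R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹.

All regression targets are ΔΔG‡ in kcal/mol; e.e. inputs are converted at
each record's temperature (default 298.15 K when a record specifies none —
consistent with the room-temperature conversions the field usually reports).
The conversion is odd and strictly increasing; its inverse is
`tanh(ΔΔG‡/2RT)`, implemented overflow-safe.

## Conformer handling

A structure (radical-capture TS, Ni(III) intermediate, reductive-elimination
TS, or a cheap surrogate) arrives as a multi-frame XYZ ensemble with one
free energy per conformer. Processing order:

1. **Deduplication** — greedy leader clustering in ascending energy order on
   heavy-atom Kabsch RMSD (default threshold 0.25 Å, window 10 kcal/mol).
   The greedy scheme is deterministic, O(kN), and idempotent; it makes no
   claim of equivalence with hierarchical clustering methods, which is
   acceptable here because only aggregated descriptor statistics consume
   the result. Hydrogens are excluded from the RMSD by default (they jitter
   the most); configurable.
2. **Energy window** — conformers above G_min + 5 kcal/mol are dropped
   before descriptor aggregation (10 kcal/mol at the dedup stage).
3. **Boltzmann weights** — w_i ∝ exp(−(G_i − G_min)/RT), computed relative
   to the ensemble minimum so adding a constant to all energies changes
   nothing. Filtering then renormalizing equals weighting the survivors
   directly.

## Descriptor catalogue

The default catalogue holds 189 descriptors: 114 steric/geometric (30
distances, 25 angles, 20 dihedrals, 12 buried volumes, 15 Sterimol values,
12 SASA values) and 75 electronic (orbital energies, global hardness, and
per-atom charges, spin densities and dispersion potentials passed through
from upstream quantum chemistry). Four statistics per descriptor — minimum,
maximum, Boltzmann-weighted average, lowest-energy-conformer value — give
756 values per structure. The compact reaction representation keeps
min/max/Boltzmann for steric descriptors and the Boltzmann average only for
electronic ones; concatenated over the three mechanism stages this is
3 × (114×3 + 75) = 1,251 provenance-tagged columns (`name__STAGE__agg`).
Atom indices in catalogue files are 1-based (chemistry convention), 0-based
internally.

Numerical choices:

* **%V_bur** — uniform Cartesian grid (default 0.05 Å spacing) restricted to
  the sphere; occupancy is the union of Bondi van-der-Waals spheres scaled
  by 1.17 (the common buried-volume convention), the center atom excluded.
  Grid integration agrees with 10⁶-point Monte-Carlo integration to well
  under 0.5 percentage points at the default spacing.
* **Sterimol** — axis from base to attached atom; L from the base atom with
  no historical +0.40 Å correction (modern convention); unscaled Bondi
  radii. B1 by a 1°-step rotational scan of the perpendicular plane with a
  0.005°-step local refinement, which matches a 0.1° brute-force scan to
  1×10⁻³ Å. A sphere cutoff (4.5 Å in the default catalogue) restricts the
  atoms considered.
* **SASA** — Shrake–Rupley with a deterministic Fibonacci lattice (960
  points/atom, probe 1.4 Å); agrees with 10⁵-point Monte-Carlo sampling
  within 1%.
* Degenerate geometry (colinear dihedral atoms, coincident Sterimol axis
  atoms) raises an error naming the offending descriptor definition.

## Model selection and ensembling

Targets are stratified by quantile binning (4 bins by default; stable
rank-order fallback under heavy ties) so every fold spans the selectivity
range. The selection pipeline is combinatorial, not regularized:

1. **Boruta** reduction: each iteration appends a permuted shadow copy of
   every surviving column, fits a random forest (150 trees,
   max_features = 1/3, the classic regression default), and scores a hit
   for features beating the best shadow importance (mean impurity decrease
   by default; out-of-sample permutation importance available). One-sided
   binomial tests, Bonferroni-adjusted across the input features as in the
   canonical algorithm, confirm or reject; rejected features leave the
   model between iterations. Tentative features are retained for the
   search stage — the scheme is all-relevant, not minimal.
2. **Exhaustive subset search**: every k-descriptor combination (default
   k = 4, guard at 10⁶ combinations) is scored by repeated stratified
   outer folds (5 folds × 10 repeats by default; with the combination
   fixed, the inner loop of the nested scheme has nothing left to choose
   and collapses). Ranking is by mean test RMSE, ties broken by fewer
   features then name order; combinations whose standardized design has
   condition number above 10⁸ are skipped.
3. **Ensemble**: the top five models are refit on all data and weighted by
   inverse mean-test-RMSE (better models weigh more; weighting directly by
   RMSE would invert model quality). Predictions report the weighted mean
   and, as the uncertainty, the unweighted standard deviation of the
   member predictions. A zero-RMSE member takes all the weight, with a
   warning.

Model comparison uses Dietterich's 5×2cv paired t-test
(t = d₁⁽¹⁾ / sqrt(Σ sᵢ²/5), 5 d.f.; p = 1 by convention when every split
ties) and one-way ANOVA over per-model error groups (guarded for
zero-within-variance groups). **Measured calibration**: on null regression
data the ANOVA rejects at 0.043; the 5×2cv t-test rejects at 0.08–0.18
depending on n and the null design. The inflation is structural, not an
implementation artifact — the statistic's denominator underestimates
Var(d₁⁽¹⁾) whenever the two half-fold differences of a replication are
positively correlated, which they are for small-n regression RMSE (under
ideal i.i.d.-normal differences the same formula is conservative, 0.028).
Treat its p-values as indicative rather than exact.

**LORO** (leave-one-reaction-out) retrains the entire pipeline — selection
included — with one reaction class held out, so nothing leaks; reduced CV
repeats keep it tractable (configurable). Single-row hold-outs report MAE
only; R² is undefined there.

## Nonlinear descriptor search

A compact SISSO-style core: operator expansion (defaults +, −, ×, ÷, x²,
√|x|, log|x|, |x|, 1/x; depth ≤ 2 hard cap; candidates with non-finite
values on the data dropped; commutative children canonicalized before
dedup; division of a subtree by itself excluded; optional unit tags forbid
sums across units), sure independence screening by |Pearson r| (default 50
survivors, ties by name), then exhaustive sparse-model selection with the
same CV machinery (default up to 4 terms). With an empty operator set the
whole pipeline reduces exactly to subset search over base features. The
published multi-residual, multi-tier SISSO iterations are out of scope.

## Active learning

Gaussian-process regression (scikit-learn, Matérn-5/2 with one shared
length scale — ARD off for sparse data — plus a white-noise term floored at
1×10⁻¹⁰; features standardized internally; marginal-likelihood maximization
with 3 seeded restarts). Batches are selected greedily with the
constant-liar scheme: pick the expected-improvement argmax, hallucinate its
posterior mean as an observation, refit with frozen hyperparameters,
repeat; hyperparameters are re-optimized only between rounds. EI uses the
maximization convention (higher ΔΔG‡ is better) and collapses to
max(μ − f*, 0) at zero posterior sd. The campaign stops when the mean EI of
a proposed batch divided by |incumbent ΔΔG‡| falls below 0.05 (the
normalization of the "about 5%" diminishing-return rule is this package's
own choice) or at the round budget. The incumbent trajectory is
non-decreasing by construction.

## Synthetic benchmarks: what they show and what they do not

The generator emulates (i) conformer ensembles as a template geometry plus
isotropic Gaussian jitter (default sd 0.05 Å) with exponential relative
free energies (mean 2 kcal/mol, a typical conformer-energy spread) and
plausible electronic properties; (ii) ligand libraries over the compact
representation's column names with a shared latent factor per mechanism
stage (ρ = 0.3) to mimic descriptor collinearity; (iii) planted selectivity
truths — linear, quotient, or nonlinear composite — rescaled to a 0.8
kcal/mol signal spread (about 25–90% e.e. at room temperature) with
Gaussian noise at 10% of the signal sd by default. All generators are pure
functions of (spec, seed).

Two identifiability choices deserve note. Planted linear coefficients have
magnitude in (1, 2): a near-zero coefficient would make a "4-feature truth"
effectively 3-feature. And the signal carriers are drawn without the stage
latent: a carrier whose own effect cancels against its block's shared
factor has near-zero marginal correlation with the target and is invisible
to any importance screen — the benchmark would then probe an accidental
sign pattern, not the pipeline. Bystander columns keep the full block
structure.

Benchmark problem sizes are desk-scale by design: 60 training reactions
(plus 15 held out) for recovery, 40-column libraries, 80 rows for the
quotient search, a 100-candidate pool with 10 warm starts and 5-ligand
batches for active learning, 10 seeds per claim. Passing these benchmarks
shows the pipeline's selection consistency, error control and sample
efficiency under known ground truth with realistic collinearity and noise.
It does not show that real reaction data satisfy a sparse linear (or
quotient) model, that real descriptor distributions match the synthetic
ones, or anything about the upstream quantum chemistry.

Measured behavior at those sizes: the recovery pipeline ranks the true
4-descriptor subset first in 8/10 seeds — the misses are seeds where one
carrier's realized marginal correlation drops to ~0.2, genuinely hard at
n = 60 — with median held-out ensemble RMSE ≈ 0.13 kcal/mol against a 0.08
noise floor (the ensemble's weaker members widen errors relative to the
best single model; that is the price of the uncertainty estimate). The EI
campaign locates the pool optimum in 10/10 seeds within 30% of the pool
evaluated and never trails random selection at equal budget.

## Known limitations

* Descriptor definitions index template-conserved atoms; there is no
  automatic atom mapping across ligand scaffolds.
* Electronic descriptors are pass-through values; no electronic-structure
  computation happens here.
* The 5×2cv t-test's anticonservativeness in small-n regression (above).
* The greedy RMSD dedup and the constant-liar batch are deliberate
  simplifications of clustering and of true q-EI, chosen for determinism
  and testability.
* Excel sheets from deposited datasets are not parsed directly; convert to
  the documented CSV schema first.
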