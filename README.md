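# enantiokit

Mechanism-informed descriptors and transferable machine-learning models of
enantioselectivity for asymmetric catalysis, aimed at the workflow of
Ni-catalysed cross-electrophile coupling but agnostic to the chemistry
upstream of it.

Predicting which chiral ligand gives high enantiomeric excess is a
free-energy problem: selectivity is set by the gap between the two
diastereomeric stereocontrolling transition states,
ΔΔG‡ = RT·ln((1+ee)/(1−ee)). enantiokit takes over where quantum chemistry
stops. Conformer ensembles of the catalytically relevant species — the
radical-capture TS (**TSRC**), the Ni(III) intermediate (**Int**) and the
reductive-elimination TS (**TSRE**), or cheap surrogates — are condensed
into steric, geometric and electronic descriptors (percent buried volume,
Sterimol L/B1/B5, solvent-accessible surface area, bond
lengths/angles/dihedrals, frontier-orbital energies and global hardness
η = ε_LUMO − ε_HOMO, atomic charges, spin densities, dispersion
potentials), each aggregated over the Boltzmann-weighted conformer ensemble
(min / max / Boltzmann average / lowest-energy value; 756 values per
structure, 1,251 for the concatenated three-stage representation). On top
of that representation the package provides:

* **Sparse multivariate linear models** — Boruta shadow-feature reduction,
  exhaustive small-subset search under repeated stratified cross-validation,
  and a 5-member inverse-RMSE-weighted ensemble whose member spread is the
  prediction uncertainty;
* **Model comparison** — Dietterich's 5×2cv paired t-test and one-way ANOVA;
* **Transfer analysis** — leave-one-reaction-out (LORO) retraining and
  feature-provenance frequency analysis across mechanism stages;
* **Nonlinear descriptors** — a SISSO-style operator expansion with sure
  independence screening and exhaustive sparse selection;
* **Active learning** — Gaussian-process regression (Matérn-5/2) with
  expected-improvement batch selection, a constant-liar scheme for batches,
  and a diminishing-return stop rule;
* **Synthetic benchmarks** — generators for conformer ensembles and ligand
  libraries with planted selectivity truths, so every stage is testable
  without any quantum chemistry.

It is a library first (`import enantiokit`), with short narrative scripts
under `examples/` and a thin `enantiokit` command-line wrapper
(`synth`, `featurize`, `represent`, `convert-ee`, `reduce`, `select`,
`train-ensemble`, `screen`, `loro`, `sisso`, `al-run`).

## Worked example

`examples/03_model_selection_and_ensemble.py` plants a hidden 4-descriptor
linear truth in a synthetic 40-column ligand library (60 training reactions,
noise at 10% of the signal spread) and runs the full selection pipeline:

```text
best 4-descriptor model: ('d_1_2__Int__max', 'd_1_2__TSRC__min', 'd_3_4__TSRC__min', 'd_5_6__TSRE__min')
  mean test RMSE 0.071 ± 0.014 kcal/mol, adj R² 0.994
hidden truth was: ('d_1_2__Int__max', 'd_1_2__TSRC__min', 'd_3_4__TSRC__min', 'd_5_6__TSRE__min')
ensemble held-out RMSE: 0.109 kcal/mol (noise floor 0.080)
top screening candidate: lig_060 predicted 0.72 ± 0.13 kcal/mol
stage usage across ensemble members: {'TSRE': 9, 'TSRC': 6, 'Int': 5}
```

The top-ranked combination is exactly the planted truth; its cross-validated
test RMSE (0.071 kcal/mol) sits near the planted noise floor. On 15 unseen
ligands the 5-member ensemble predicts ΔΔG‡ to 0.109 kcal/mol — a few
hundredths above the floor, the price of carrying an uncertainty estimate —
and the virtual screen ranks candidates by predicted ΔΔG‡ with a
one-spread improvement margin. The stage histogram says which mechanism
stage the predictive descriptors come from, the package's analogue of
asking *where* stereoinduction is decided.

Other examples: conformer processing and the 756-value structure
fingerprint (`01`), e.e.↔ΔΔG‡ conversion (`02`), quotient-descriptor
recovery with the SISSO-style search (`04`), and an expected-improvement
screening campaign with its stop rule (`05`).

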