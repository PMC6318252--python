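# Methods

## Exchange model

Backbone amide hydrogen exchange follows the two-state opening model:
a closed amide opens at rate `k_open` (1/s), recloses at `k_close`, and
exchanges chemically from the open state at the intrinsic rate `k_int`.
The observed rate is

    k_ex = k_open * k_int / (k_close + k_open + k_int)

In the EX2 regime (`k_close >> k_open, k_int`) this reduces to
`k_ex = K_open * k_int` with `K_open = k_open/k_close`; in the EX1 regime
(`k_int >> k_close`) to `k_ex = k_open`. The relative error of the EX2
approximation is `(k_open + k_int)/(k_close + k_open + k_int)`, so the
1 %-agreement checks in the tests require the dominating rate to exceed
100x the *sum* of the competing rates (at 100x the max alone the error can
reach 2 %).

The protection factor is `PF = k_int/k_ex ≈ 1/K_open` and
`DeltaG_ex = R T ln PF` with `R = 1.9872e-3 kcal/(mol K)`. `logPF` is
base-10 throughout the public interface; relations stated on the natural
scale (the opening free energy, the phenomenological approximation) are
converted explicitly at the interface, preventing silent factor-of-2.303
errors. `k_ex = 0` maps to an infinite-protection sentinel (`math.inf`),
not an exception, and propagates as zero uptake.

## Intrinsic rates

`k_int` uses the Bai et al. poly-DL-alanine parameterization for exchange
into D2O: acid, base and water catalysis with reference log10 rates 1.62
and 10.05 (1/(M min)) and -1.5 (1/min) at 293 K, pK(D2O) = 15.05,
side-chain factors for the residue bearing the amide and its predecessor,
charged-termini corrections, and per-term Arrhenius correction with
activation energies 14/17/19 kcal/mol. Asp/Glu factors are the carboxylate
forms and His the protonated form; titration with pD is not modelled, and
pK(D2O) is held fixed over the modest temperature ranges involved.
Defaults are pD 7.0 and 293.15 K, exposed everywhere, since published PF
datasets rarely state their exact conditions; rates are stored in 1/s (the
CLI can emit 1/min). Position 1 of a chain is rejected (its amide
back-exchanges too fast to record) and proline has no amide hydrogen.

## Structural covariates

* **Burial** `N_C`: non-hydrogen atoms within an inclusive 6.5 A cutoff of
  the amide nitrogen, excluding the nitrogen itself. Waters and hetero
  atoms are excluded by default (burial measures protein packing); an
  `include_het` flag exists for sensitivity checks, and a backbone-only
  scope restricts to N/CA/C/O for the backbone-calibrated phenomenological
  preset.
* **Secondary structure** from the PDB file's HELIX/SHEET records: alpha-
  and 3/10-helices map to `helix`, strands and bridges to `beta-sheet`,
  everything else to `no`. Pi-helices map to `helix` as the closest of the
  three categories. No DSSP recomputation is attempted.
* **Hydrogen bonding**: the amide N-H donor against O acceptors with a
  relaxed geometric criterion, N...O <= 3.5 A and D-H...A angle >= 120 deg,
  the amide H taken from the file or built from backbone geometry (on the
  bisector opposite CA and the preceding carbonyl C, N-H 1.01 A).
  Covalently adjacent oxygens (the residue's own and the preceding
  carbonyl) are excluded. Categories follow the acceptor type with
  precedence main-chain O > side-chain O > water when several qualify
  (main-chain acceptors dominate folded proteins), and `N_H` counts all
  qualifying acceptors. These thresholds approximate common
  molecular-graphics defaults; they are configurable
  (`HBondCriteria`) and no exact reproduction of any particular program is
  claimed.
* **HX-enabling motion** from a DeltaG_ex vs denaturant series: |slope|
  below 0.5 kcal/mol/M calls local fluctuations (`L`); otherwise a
  significant quadratic lack-of-fit term (alpha = 0.05) calls partial
  unfolding (`UD`); otherwise strong linear dependence calls global
  unfolding (`UD+EX1`). The literature states these rules qualitatively
  only, so both thresholds are exposed configuration; `EX1` is an
  experimental elevated-pH label and is only ever supplied via annotation
  tables, never produced by the classifier.

## The log-linear model

The design uses indicator coding with reference levels motion `L`, SS
`no`, H-bond `no`, plus the burial count. Fitting is ordinary least
squares (statsmodels) with backward elimination at p < 0.05. The default
elimination unit is the whole categorical factor — a factor survives while
any of its levels is significant, and the factor whose most significant
level is weakest is removed first. This is the only rule consistent with
the published coefficient table, which retains the beta-sheet level at
p = 0.068 alongside a strongly significant helix level; term-wise
elimination is available for sensitivity analysis. Eliminated terms are
reported with their last fitted estimate but flagged unretained and
contribute zero to prediction. Constant design columns (unobserved
categories) are dropped before fitting with a warning naming them. The
published estimates ship as the preset `poppet-2018`; refitting is a
separate, explicit operation.

The phenomenological approximation `ln PF = beta_H N_H + beta_C N_C` ships
with both published presets (all-atoms: beta_C = 0.35, beta_H = 2.0;
backbone-only: beta_C = 1.0, beta_H = 5.0). Its output is treated as a
natural log and divided by ln 10 at the interface; an `assume_log10` flag
reproduces a literal base-10 reading.

COREX-style aggregation consumes a user-supplied microstate ensemble
(state free energies plus per-residue folded/exposed flags). Probabilities
are Boltzmann weights normalised with log-sum-exp, invariant to a common
free-energy shift. The PF of a residue is the probability sum over states
where it is folded and unexposed divided by the sum over states where it
is unfolded and exposed, each reduced by Pr(i), the probability that the
residue is natively accessible; Pr(i) cannot be derived from the flags
alone and defaults to 0 with a warning when the generator does not supply
it. A non-positive denominator yields the infinite-protection sentinel.
Ensemble *generation* (ASA-based free energies, conformational entropy,
partition enumeration) is out of scope.

## Deuterium uptake

Residue-level uptake is `D_i(t) = 1 - exp(-(k_int,i/PF_i) t)`; peptide
uptake sums residues 2..n (only the first residue is excluded — some HX
conventions exclude two, this package does not), prolines contribute zero
and reduce the theoretical maximum below n-1. Back exchange is an optional
scalar multiplier (default 1.0) on the peptide total; no per-residue
back-exchange model is attempted. The default labelling grid is 16
geometrically spaced points from 30 s to 16 days (only the endpoints are
fixed by convention; geometric spacing matches the logarithmic sampling
universally used in HDX time courses, and any explicit grid can be
supplied). Uptake profiles are compared as signed per-time differences
with min/max summaries.

## Accuracy metrics

Predicted-vs-measured comparisons report signed differences
(predicted - measured), their mean absolute and maximum absolute values,
and the Pearson correlation on the logPF scale (a PF-scale option exists
but is non-default, as log-scale scatter is the field's standard view).
"Average difference" means the mean absolute difference; the signed mean
is reported alongside. Deuteration-scale error composes the uptake
simulation for two PF sources over the same peptides and grid and emits a
tidy long-format table.

## Synthetic data

The generator draws covariates from a configurable categorical/count
distribution and the measured logPF from the model's own assumed
structure: linear predictor plus N(0, sigma^2) noise. Defaults mirror a
typical folded-protein HX dataset: burial centred at 59.1 (the reported
training-set average) with SD 15, ~85 % of amides hydrogen-bonded to
main-chain oxygens, all four motion and all three SS categories
well-populated so the full design is estimable. The default noise
sigma = 0.3 logPF units is of the order of the residual scatter a fit of
this kind leaves. Synthetic structures are an ideal poly-Ala helix
(phi = -57.8, psi = -47.0, giving O(i)...N(i+4) = 3.05 A so the i -> i-4
hydrogen-bond geometry holds), an ideal extended strand, and probe-centred
point clouds with caller-specified distances; all are seed-deterministic.

What passing on synthetic data does and does not show: the generator
draws from exactly the model family being fitted, with independent
residues, no covariate measurement error, no motion-category
misclassification and no back exchange, so recovery and accuracy results
certify the estimation and propagation machinery — not predictive accuracy
on real proteins, which depends on covariate quality and on the model
being adequate.

## Problem sizes and numerical choices

Statistical tests use n = 43 (30 train / 13 test) to mirror the published
study scale, n = 200-500 for recovery and coverage checks, 30-100 seeds
for replicate-level assertions; the full suite runs in a few seconds.
Boltzmann aggregation is log-sum-exp stabilised and exact to 1e-12
normalisation at 10^4 states. Distance cutoffs are inclusive; altloc ties
resolve to 'A'; only MODEL 1 of multi-model PDB files is read; author
residue numbering (with insertion codes) is the coordinate system
everywhere.

## Known limitations

- The H-bond criterion is a geometric approximation, not a reproduction of
  any specific assignment program.
- Intrinsic rates ignore side-chain titration with pD and the temperature
  dependence of the D2O ion product.
- The published coefficient preset was trained on 30 amides of one
  protein; it is a demonstrator, not a general-purpose predictor.
- EX1 bimodal isotope envelopes, per-residue back exchange and microstate
  ensemble generation are out of scope.
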