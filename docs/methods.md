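# Methods

## The compartmental autocrine model

The model describes a monolayer of cells at the bottom of a 100 µL
culture well (0.32 cm² growth area, 3×10⁴ cells by default) that sheds
one or more ErbB-family ligands and recaptures them through surface
receptors. The medium is split into three well-mixed compartments
stacked over the monolayer:

* **V_S** — a 2 µm pericellular layer in contact with the cell surface,
* **V_B** — a 50 µm unstirred boundary layer,
* **V_BB** — the remaining bulk supernatant (≈98 µL).

Transport between adjacent compartments is diffusion-limited linear
exchange, Δ_ij·(L_i − L_j) with Δ_ij = D·A/δ_ij, where δ_ij is the mean
thickness of the two adjoining layers. Δ is therefore proportional to
the species' diffusivity, and each diffusing species (ligand, decoy
antibody, inhibitor) carries its own Δ pair. Modeling V_S as a single
slab over the monolayer rather than per-cell shells is exact in this
well-level mean-field description and avoids single-cell geometry the
data do not constrain.

Per ligand, the surface species (molecules/cell) obey

    dR/dt = q_R − k_t·R − Σ k_on·L_S·R + Σ k_off·C
    dC/dt = k_on·L_S·R − (k_off + k_e)·C

with ligand shedding entering V_S as a flux k_Q·P_free per cell and
internalization k_e·C as the terminal sink. Cumulative released and
internalized ligand are integrated as explicit states so the capture
fraction — cumulative internalized / cumulative released at 24 h — is
read directly off the trajectory, and so mass balance can be audited:
for every ligand, released + initial must equal free (all compartments)
+ antibody-bound + receptor-bound + internalized at every output time.
`conservation_residual` evaluates this; converged runs sit at ~1e-15,
and the test suite enforces ≤1e-6.

Interventions:

* **Decoy antibody** — a monovalent 1:1 reversible binder (default
  K_D = 0.1 nM, k_on = 1e6 M⁻¹min⁻¹, D = 4e-7 cm²/s, IgG-like), dosed
  into the bulk compartments (V_B, V_BB) and reaching V_S by diffusion.
  Bulk initialization mirrors adding antibody to the medium; because
  antibody diffusion into the 2 µm layer equilibrates within seconds,
  initializing V_S as well changes responses negligibly.
* **Receptor blockade** (mAb225 emulation) — instantaneous removal of a
  fraction of receptors and their synthesis, not a competing binder; the
  experiments it emulates use the antibody purely as a capture on/off
  switch.
* **Sheddase inhibitor** — binds free protease reversibly
  (k_off = K_i·k_on, with k_on = 1e6 M⁻¹min⁻¹ by default, mirroring how
  off-rates are estimated from measured IC50s); the shedding flux scales
  with the free-protease fraction. Only the product k_Q·P enters the
  uninhibited dynamics, so the absolute protease copy number (default
  5000/cell, admissible 500–50,000) matters solely for inhibitor
  stoichiometry — the tests verify capture is insensitive to P across
  that 100-fold range at fixed flux.

## Default parameterization

All defaults live in `src/autoloop/defaults.yaml` (dumped by
`autoloop defaults`) and every value is config-overridable; sweeps, not
point values, carry the scientific conclusions. Kinetic constants are
standard EGFR-system values: k_on = 1e8 M⁻¹min⁻¹, k_t = 0.03 min⁻¹,
k_e = 0.15 min⁻¹, R0 = 2×10⁵/cell (EGFR-overexpressing line),
D_ligand = 1e-6 cm²/s. The two shipped ligands differ by two orders of
magnitude in affinity (HB-EGF-like 1 nM, AREG-like 100 nM), matching
the known spread between those ligands' EGFR binding. Release rates
(HB-EGF 10, AREG 70 molecules/cell/min) are on the scale that 24-h
supernatant accumulation under receptor blockade measures in this cell
system (~1–6 ng/mL per 1.5×10⁶ cells in 500 µL) and reproduce its two
calibration anchors: near-complete HB-EGF recapture with largely free
AREG, and an HB-EGF share of total 24-h receptor signaling of ~35%.
Soluble-ligand molecular weights default to 10 kDa (HB-EGF) and 11 kDa
(AREG) for molar conversion; antibody doses convert at 150 kDa
(10 µg/mL ≈ 67 nM).

"Total receptor signaling" is defined as total ligand–receptor
complexes per cell at t = 24 h. A time-integrated alternative is
available (`metric="integrated"` in the dose-response functions); the
two give the same qualitative orderings here because the system reaches
its quasi-steady complex level within the first hours.

## Dose–response and IC50

The response metric is the fractional reduction of total complexes at
24 h, 1 − complexes(dose)/complexes(0). The ODE model is the ground
truth for these curves, so IC50 is obtained by log-linear interpolation
of the 50% crossing rather than a parametric Hill fit; a curve that
never crosses 0.5 yields an explicit one-sided bound, never a silent
extrapolation. The default dose grid spans 1e-2–1e3 × the decoy K_D or
inhibitor K_i; for high-affinity ligands the decoy crossing can sit
above that range, in which case the result carries the bound and
callers (as the tests do) should pass a wider grid.

## From immunoassays to rates

Release rates are computed exactly as the accumulation experiment
implies: rate = max(0, conc − background)·V·N_A/(MW·cells·t), with the
metalloproteinase-inhibitor (BB94-style) control subtracted per arm and
negative corrected values clamped to zero with an explicit flag.
Measurements taken without receptor blockade carry a capture-confound
warning rather than an error. The experimental capture ratio
(net unblocked / net blocked concentration) is the measured fraction of
bulk free ligand; its model counterpart `free_ligand_fraction` runs the
paired ±blockade simulations. The two definitions differ by ligand in
transit or still receptor-bound at harvest; across the affinity range
this residual stays below 0.05 and the round-trip tests enforce that.
Receptor counts invert a bead standard curve by piecewise-linear
interpolation (exact at calibrators), with out-of-range signals
extrapolated from the nearest segment and flagged. `calibrate_system`
tunes each ligand's K_D by bounded scalar search on log10 K_D
(0.1 nM–10 µM) against a measured capture ratio, flags solutions at the
search boundary, and reports (never silently accepts) residuals above
0.1.

## Cue-signal-response attribution

Cleavage rates are replicate-mean OLS slopes of the FRET time courses
(replicates with <2 finite points are dropped with a warning). Protease
activities solve rates ≈ signature·activities by non-negative least
squares per condition; with ensembling (default subset size = one less
than the number of substrates) the solution is averaged over all
full-rank substrate subsets and the across-subset dispersion reported.
This is deliberately a reduced, faithful variant of published
FRET-deconvolution machinery — base NNLS plus subset ensembling — not a
reimplementation of any specific tool's regularization. The signature
matrix is an input; the shipped 7×4 matrix is synthetic (documented in
`synthetic_data.default_signature`) with condition number of a few,
the regime where deconvolution is informative.

Correlations are Pearson r across condition-level replicate means, with
p from the exact t-transform on n−2 degrees of freedom and pairwise
missing-value exclusion (n reported per pair). Zero-variance vectors
yield an undefined (missing) correlation, never a fabricated 0. No
multiple-testing correction is applied across the map, matching how
such screens report raw two-tailed p-values. Sheddase ranking sorts by
descending r with deterministic tie-breaks (ascending p, then label).

## Inhibitor potency

Initial velocities are OLS slopes over a configurable early-linear
window with a quadratic-term t-statistic as curvature diagnostic.
Dose–response fitting uses the one-site hyperbola first; when the
fitted IC50 falls within 10× the enzyme concentration, free and total
inhibitor diverge and the Morrison tight-binding quadratic is refit and
reported (its reported IC50 adds E/2 to the fitted K_app). K_i applies
the competitive correction IC50/(1 + S/K_M) when a substrate K_M is
supplied and otherwise equals the fitted constant with an explicit
"uncorrected" flag — at substrate far below K_M the two coincide.
Confidence intervals come from a seeded residual bootstrap.

"No detectable inhibition" means <10% rate reduction at the top dose.
With few replicates the observed top-dose pair is a noisy statistic, so
after an initial screen the decision uses the fitted curve's predicted
reduction at the top dose, which pools all doses; flat-at-5%-noise
curves are then flagged in ≥99/100 seeds without misclassifying real
inhibition whose IC50 lies inside the dose range. Grossly non-monotone
(activating) series raise a fit-quality error rather than returning a
potency.

## Synthetic data and what passing tests mean

The generators emulate the study design: 8 cues × ±receptor blockade =
16 conditions, 7 FRET substrates × 4 replicates × 5 timepoints over
3 h, 3 ELISA replicates, 6-point 3-fold inhibitor dilutions at 5 nM
enzyme and 15 µM substrate. Noise models are conventional for each
assay class — additive Gaussian scaled to signal range for
fluorescence, multiplicative log-normal (CV 10%) for immunoassays and
cell counts — because the emulated experiments report only replicate
counts and SEMs, not noise structure. Every generator is a pure
function of (config, seed) and writes a ground-truth sidecar; recovery
tests read truth only from the sidecar.

What the generators do **not** emulate: plate-position effects,
standard-curve nonlinearity, receptor-pathway feedback on protease
activity, matrix/proteoglycan binding as an explicit species (only as
reduced effective diffusivity), or cell growth/death over the
experiment. Passing recovery tests therefore demonstrates that the
inference machinery is correct under its stated noise model, not that
real assays satisfy that model.

## Numerical choices

Stiff integration (LSODA) at rtol 1e-8 / atol 1e-12 on a fixed 241-point
output grid over 24 h; solver failures and non-finite states raise with
diagnostics rather than returning partial trajectories. There is no
randomness anywhere in the ODE layer, so repeated sweeps are
bit-identical. Simulations cost ~30–80 ms each, which keeps the full
property suite (a few hundred simulations: an 8-point affinity grid, 6-
and 4-point IC50 sweeps, the inhibitor-invariance grid, and 100-seed
recovery loops) within a few minutes on one CPU. Degenerate inputs are
errors, not defaults: zero cells, zero release when a capture fraction
is requested, and capture ratios with non-positive blocked-arm signal
all raise typed exceptions, because silently returning 0 would conflate
"nothing released" with "nothing captured".

## Known limitations

* The three-compartment mean-field geometry cannot represent lateral
  heterogeneity or single-cell microenvironments; it targets well-level
  supernatant observables.
* Receptor dimerization, downstream phosphorylation, and intracrine
  C-terminal fragment signaling are out of scope; "signaling" here is
  complex abundance.
* The decoy is monovalent; avidity effects of bivalent IgG would make
  sequestration somewhat more effective at low ligand density.
* Inhibitor K_i values fitted without a substrate K_M are lower-bound
  approximations of the true competitive K_i.
* The shipped signature and coupling matrices are synthetic stand-ins;
  applying the CSR pipeline to real panels requires measured catalytic
  efficiencies.
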