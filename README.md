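# autoloop

Quantitative tools for **autocrine ErbB-ligand signaling**: how much of a
growth factor that cells shed from their own surface do they recapture
through their own receptors — and what does that mean for therapies that
try to intercept the ligand?

Epithelial cells (the shipped defaults emulate an EGFR-overexpressing
endometriotic line cultured in a 96-well plate) continuously release
ligands such as HB-EGF and amphiregulin (AREG) by protease-mediated
ectodomain shedding. A high-affinity ligand is recaptured by surface EGFR
almost as soon as it is released, so it signals locally and barely appears
in the supernatant; a low-affinity ligand escapes into the bulk medium.
This single physicochemical difference decides whether a ligand can be
neutralized by a soluble "decoy" antibody, or is better attacked upstream
by inhibiting the sheddase that releases it.

The package contains:

* **`model_core`** — a three-compartment ODE model of a cells-in-a-well
  autocrine loop: ligand shedding at rate $k_Q P$ (molecules/cell/min)
  into a 2 µm pericellular layer, diffusion through a 50 µm boundary
  layer into the bulk (inter-compartment flux $\Delta_{ij}(L_i - L_j)$,
  $\Delta_{ij} = D A/\delta_{ij}$), reversible receptor binding
  ($k_{on}, k_{off}$, $K_D = k_{off}/k_{on}$), receptor trafficking
  ($\dot R = q_R - k_t R - k_{on} L_S R + k_{off} C$,
  $\dot C = k_{on} L_S R - (k_{off} + k_e) C$), and optional
  interventions: a 1:1 decoy antibody and a reversible sheddase
  inhibitor (free-protease fraction $K_i/(K_i + I)$ scales release).
  Key readout: the **capture fraction**, cumulative internalized /
  cumulative released ligand over 24 h.
* **`dose_response`** — decoy and inhibitor dose–response curves
  (fractional reduction of ligand–receptor complexes at 24 h), IC50 by
  log-linear interpolation, and parameter sweeps.
* **`parameterization`** — converts supernatant ELISA accumulations
  (± receptor-blocking antibody, background-corrected against a
  broad-spectrum metalloproteinase inhibitor control) and bead-calibrated
  receptor staining into model rates, and tunes ligand $K_D$ to
  reproduce measured capture ratios.
* **`csr_pipeline`** — cue-signal-response analysis: cleavage rates from
  FRET substrate panels (OLS slope of fluorescence), protease-activity
  deconvolution through a catalytic-efficiency signature matrix
  (non-negative least squares with optional substrate-subset
  ensembling), per-cell response normalization, and Pearson
  protease×substrate correlation maps with two-tailed t-test p-values
  ($t = r\sqrt{(n-2)/(1-r^2)}$) to rank candidate sheddases.
* **`enzyme_kinetics`** — inhibitor potency from recombinant-enzyme
  dilution series: hyperbolic $v = v_0\,(1 - I/(I+\mathrm{IC}_{50}))$
  and Morrison tight-binding fits, $K_i$ with or without the
  $1 + S/K_M$ competitive correction, bootstrap CIs, and
  no-detectable-inhibition bounds for specificity panels.
* **`synthetic_data`** — seeded generators for every input above, each
  with a ground-truth sidecar, so the full pipeline is testable without
  any external data.

## Worked example

```python
from autoloop import model_core as mc

system = mc.default_system()          # two-ligand 12Z-like defaults
traj = mc.simulate(system)            # 24 h, stiff solver
for lig in ("HB-EGF", "AREG"):
    print(lig, round(mc.capture_fraction(traj, lig), 3))
print("total complexes/cell:", round(traj.complexes()[-1], 1))
print("mass-balance residual:", mc.conservation_residual(traj))
```

prints

```
HB-EGF 0.905
AREG 0.184
total complexes/cell: 184.9
mass-balance residual: 5.052748343182934e-16
```

i.e. ~90% of the high-affinity ligand (K_D = 1 nM) is recaptured before
it can escape, while ~82% of the low-affinity ligand (K_D = 100 nM)
accumulates free in the medium. The same asymmetry drives decoy-antibody
efficacy: at 10 µg/mL (67 nM) of a 0.1 nM-affinity decoy, the simulated
24 h complex inhibition is 0.76 for the AREG-like ligand but only 0.24
for the HB-EGF-like one — sequestration cannot outrun recapture inside
the pericellular layer. A sheddase inhibitor shows no such affinity
dependence: its IC50 equals its $K_i$ regardless of ligand $K_D$.

The same workflow is scriptable from the shell:

```bash
autoloop simulate --out out/            # trajectory.csv + summary.json
autoloop defaults                       # provenance dump of all defaults
autoloop decoy-sweep --param ligands.HB-EGF.kd_nM \
    --grid 0.1,1,10,100 --doses 0.01,0.1,1,10,100,1000,10000 --out sweep.csv
```

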