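# Shipped 12Z-like default parameterization.
#
# Units: time min; concentration nM; k_on 1/(nM*min) (0.1 == 1e8 M^-1 min^-1);
# diffusivity cm^2/s; volumes uL; release rates molecules/cell/min.
#
# Geometry matches a 96-well culture well: 100 uL media over 0.32 cm^2,
# with a 2 um pericellular layer and a 50 um unstirred boundary layer.
# Receptor trafficking constants are standard EGFR values (constitutive
# internalization ~0.03/min, ligand-induced ~0.15/min, ~2e5 receptors/cell
# for an EGFR-overexpressing line).  Release rates are on the scale that
# 24-h supernatant accumulation under receptor blockade measures for 12Z
# (~1-6 ng/mL per 1.5e6 cells in 500 uL), with the low-affinity ligand
# (AREG-like) several-fold more abundant than the high-affinity one
# (HB-EGF-like).  Affinities differ by two orders of magnitude, consistent
# with the known spread between HB-EGF and AREG binding to EGFR.
geometry:
  well_volume_ul: 100.0
  cell_layer_um: 2.0
  boundary_layer_um: 50.0
  well_area_cm2: 0.32
  n_cells: 3.0e4
receptor:
  r0: 2.0e5
  kt_per_min: 0.03
  ke_per_min: 0.15
  blockade_fraction: 0.0
protease:
  p_per_cell: 5000.0        # admissible 500-50,000; results insensitive
ligands:
  - name: HB-EGF
    kd_nM: 1.0
    kon_per_nM_min: 0.1
    d_cm2_s: 1.0e-6
    release_rate: 10.0
    mw_kda: 10.0
  - name: AREG
    kd_nM: 100.0
    kon_per_nM_min: 0.1
    d_cm2_s: 1.0e-6
    release_rate: 70.0
    mw_kda: 11.0
# Interventions are off unless a section is supplied in the user config:
# decoy:      {kd_nM: 0.1, kon_per_nM_min: 1.0e-3, d_cm2_s: 4.0e-7, dose_nM: 0}
# inhibitor:  {ki_nM: 430.0, kon_per_nM_min: 1.0e-3, d_cm2_s: 1.0e-6, dose_nM: 0}
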