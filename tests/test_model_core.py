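"""Core compartmental model: construction, integration, mass balance."""

import dataclasses as dc

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from autoloop import model_core as mc


class TestBuildSystem:
    def test_volumes_partition_the_well(self):
        geo = mc.ModelGeometry(well_volume_ul=100.0, cell_layer_um=2.0,
                               boundary_layer_um=50.0)
        total = geo.v_s_l + geo.v_b_l + geo.v_bb_l
        assert total == pytest.approx(100e-6, rel=1e-12)
        assert geo.v_s_l > 0 and geo.v_b_l > 0 and geo.v_bb_l > 0

    def test_transport_linear_in_diffusivity(self):
        geo = mc.ModelGeometry()
        d1 = geo.transport_l_per_min(1e-6)
        d2 = geo.transport_l_per_min(2e-6)
        assert d2[0] == pytest.approx(2 * d1[0], rel=1e-12)
        assert d2[1] == pytest.approx(2 * d1[1], rel=1e-12)

    def test_no_cells_rejected(self):
        with pytest.raises(mc.ConfigError, match="n_cells"):
            mc.build_system({"geometry": {"n_cells": 0}})

    def test_koff_derived_from_kd_and_kon(self):
        # k_on 1e8 M^-1 min^-1 and K_D 1 nM imply k_off 0.1 min^-1
        lig = mc.LigandSpec(kd_nM=1.0, kon_per_nM_min=0.1)
        assert lig.koff_per_min == pytest.approx(0.1, rel=1e-12)

    def test_inconsistent_binding_triple_rejected(self):
        with pytest.raises(mc.ConfigError, match="conflicts"):
            mc.LigandSpec(kd_nM=1.0, kon_per_nM_min=0.1, koff_per_min=0.5)

    def test_unknown_keys_rejected(self):
        with pytest.raises(mc.ConfigError, match="unknown"):
            mc.build_system({"geometry": {"wellvolume": 1.0}})
        with pytest.raises(mc.ConfigError, match="unknown"):
            mc.build_system({"geom": {}})

    def test_negative_rate_names_field(self):
        with pytest.raises(mc.ConfigError, match="release_rate"):
            mc.build_system({"ligands": [{"name": "L", "release_rate": -1.0}]})

    def test_receptor_rest_steady_state(self):
        rec = mc.ReceptorSpec(r0=2e5, kt_per_min=0.03)
        assert rec.qr_per_min / rec.kt_per_min == pytest.approx(2e5)


class TestSimulate:
    def test_null_source_stays_zero(self, single_ligand):
        traj = mc.simulate(single_ligand(release_rate=0.0))
        assert np.all(traj.free_ligand_nM("L") == 0.0)
        assert np.all(traj.complexes("L") == 0.0)
        assert np.all(traj.cumulative_released("L") == 0.0)

    def test_decoy_conserved_without_sinks(self):
        # no receptors, no release: the antibody has nothing to bind
        sys0 = mc.build_system({
            "ligands": [{"name": "L", "kd_nM": 1.0, "release_rate": 0.0}],
            "receptor": {"r0": 0.0, "qr_per_min": 0.0},
            "decoy": {"dose_nM": 67.0}})
        traj = mc.simulate(sys0)
        geo = sys0.geometry
        vols = np.array([geo.v_s_l, geo.v_b_l, geo.v_bb_l])
        a = traj.states[traj._layout.i_a]
        total = (a * vols[:, None]).sum(axis=0)
        assert total == pytest.approx(total[0], rel=1e-9)

    def test_two_state_binding_matches_closed_form(self):
        # well-mixed, fixed receptor pool, no trafficking: relaxation to
        # C_eq = R_tot * L / (K_D + L) at rate k_on*L + k_off
        L0, kd, kon, r_tot = 100.0, 10.0, 0.1, 100.0
        sys0 = mc.build_system({
            "ligands": [{"name": "L", "kd_nM": kd, "kon_per_nM_min": kon,
                         "release_rate": 0.0, "initial_bulk_nM": L0,
                         "d_cm2_s": 10.0}],
            "receptor": {"r0": r_tot, "kt_per_min": 0.0, "ke_per_min": 0.0,
                         "qr_per_min": 0.0}})
        traj = mc.simulate(sys0, duration_min=1.0, n_points=201)
        geo = sys0.geometry
        l_eff = L0 * (geo.v_b_l + geo.v_bb_l) / (geo.well_volume_ul * 1e-6)
        k = kon * l_eff + kd * kon
        c_eq = r_tot * l_eff / (kd + l_eff)
        pred = c_eq * (1.0 - np.exp(-k * traj.t_min))
        # skip the first instants while the bulk mixes into the cell layer
        late = traj.t_min >= 0.05
        err = np.abs(traj.complexes("L")[late] - pred[late]) / c_eq
        assert err.max() < 1e-4

    def test_states_nonnegative(self, default_trajectory):
        assert default_trajectory.states.min() >= -default_trajectory.atol

    def test_cumulative_fluxes_nondecreasing(self, default_trajectory):
        for lig in ("HB-EGF", "AREG"):
            assert np.all(np.diff(
                default_trajectory.cumulative_released(lig)) >= 0)
            assert np.all(np.diff(
                default_trajectory.cumulative_internalized(lig)) >= -1e-12)

    def test_dense_output_grid(self, default_trajectory):
        assert len(default_trajectory.t_min) >= 200

    def test_nonpositive_duration_rejected(self, default_system):
        with pytest.raises(mc.ConfigError):
            mc.simulate(default_system, duration_min=0.0)


class TestCaptureFraction:
    def test_blockade_abolishes_capture(self, single_ligand):
        sys0 = single_ligand()
        sys0 = sys0.replace(receptor=dc.replace(sys0.receptor,
                                                blockade_fraction=1.0))
        traj = mc.simulate(sys0)
        assert mc.capture_fraction(traj, "L") <= 1e-6

    def test_low_affinity_capture_below_bound(self, single_ligand):
        traj = mc.simulate(single_ligand(kd_nM=1000.0))
        assert mc.capture_fraction(traj, "L") < 0.40

    def test_zero_release_is_undefined_not_zero(self, single_ligand):
        traj = mc.simulate(single_ligand(release_rate=0.0))
        with pytest.raises(mc.UndefinedFractionError):
            mc.capture_fraction(traj, "L")

    def test_closed_system_captures_everything_eventually(self, single_ligand):
        # irreversible internalization, nothing leaves the well: at long
        # times every released molecule must end up internalized
        sys0 = single_ligand(kd_nM=0.0, kon_per_nM_min=0.1)
        traj = mc.simulate(sys0, duration_min=14400.0)
        assert mc.capture_fraction(traj, "L") > 0.99


class TestFreeLigandFraction:
    def test_zero_release_errors(self, single_ligand):
        with pytest.raises(mc.UndefinedFractionError):
            mc.free_ligand_fraction(single_ligand(release_rate=0.0), "L")

    def test_very_low_affinity_mostly_free(self, single_ligand):
        assert mc.free_ligand_fraction(single_ligand(kd_nM=1e4), "L") > 0.6

    def test_no_receptors_gives_ratio_one(self, single_ligand):
        sys0 = single_ligand()
        sys0 = sys0.replace(receptor=dc.replace(
            sys0.receptor, r0=0.0, qr_per_min=0.0))
        assert mc.free_ligand_fraction(sys0, "L") == pytest.approx(1.0,
                                                                   abs=1e-9)

    @pytest.mark.parametrize("kd", [1.0, 100.0, 1e4])
    def test_complement_tracks_capture_fraction(self, single_ligand, kd):
        # the two readouts differ only by ligand in transit or bound at 24 h
        sys0 = single_ligand(kd_nM=kd)
        fff = mc.free_ligand_fraction(sys0, "L")
        cap = mc.capture_fraction(mc.simulate(sys0), "L")
        assert abs((1.0 - fff) - cap) < 0.05


class TestConservation:
    def test_converged_residual_tiny(self, default_trajectory):
        assert mc.conservation_residual(default_trajectory) <= 1e-6

    def test_perturbed_states_detected(self, default_trajectory):
        # inflate only the cumulative-release ledger: the inventory no
        # longer accounts for 1% of the recorded supply
        states = default_trajectory.states.copy()
        states[default_trajectory._layout.i_rel] *= 1.01
        bad = dc.replace(default_trajectory, states=states)
        assert mc.conservation_residual(bad) >= 1e-3

    def test_zero_source_residual_zero(self, single_ligand):
        traj = mc.simulate(single_ligand(release_rate=0.0))
        assert mc.conservation_residual(traj) == 0.0

    def test_well_mixed_limit_matches_single_compartment(self):
        # collapsing the boundary layers (large D) must reproduce a
        # well-mixed single-compartment model of the same well
        sys0 = mc.build_system({"ligands": [
            {"name": "L", "kd_nM": 10.0, "release_rate": 10.0,
             "d_cm2_s": 1.0}]})
        traj = mc.simulate(sys0)
        conc = traj.free_ligand_nM("L")
        spread = np.abs(conc[0] - conc[2]) / np.maximum(conc[2], 1e-30)
        assert spread[-1] < 0.01

        geo, rec, lig = sys0.geometry, sys0.receptor, sys0.ligands[0]
        vol = geo.well_volume_ul * 1e-6
        conv = geo.n_cells / (mc.AVOGADRO * vol) * 1e9

        def rhs(t, y):
            r, c, l, rel, internal = y
            bind = lig.kon_per_nM_min * l * r
            unbind = lig.koff_per_min * c
            return [rec.qr_per_min - rec.kt_per_min * r - bind + unbind,
                    bind - unbind - rec.ke_per_min * c,
                    (lig.release_rate - bind + unbind) * conv,
                    lig.release_rate, rec.ke_per_min * c]

        ref = solve_ivp(rhs, (0, 1440), [rec.r0, 0, 0, 0, 0],
                        method="LSODA", rtol=1e-10, atol=1e-12)
        cap_ref = ref.y[4][-1] / ref.y[3][-1]
        assert mc.capture_fraction(traj, "L") == pytest.approx(cap_ref,
                                                               rel=1e-4)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(kd=st.floats(0.1, 1e4), release=st.floats(1.0, 200.0),
       r0=st.floats(1e4, 1e6))
def test_mass_conservation_property(kd, release, r0):
    """Every converged simulation balances release against inventory."""
    sys0 = mc.build_system({
        "ligands": [{"name": "L", "kd_nM": kd, "release_rate": release}],
        "receptor": {"r0": r0}})
    traj = mc.simulate(sys0, duration_min=360.0)
    assert mc.conservation_residual(traj) <= 1e-6
    assert traj.states.min() >= -traj.atol
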