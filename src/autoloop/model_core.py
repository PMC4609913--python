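"""Three-compartment ODE model of autocrine growth-factor signaling.

Cells sit at the bottom of a tissue-culture well and continuously shed an
ErbB-family ligand (e.g. HB-EGF or amphiregulin) from their surface via a
membrane protease.  Released ligand diffuses through two boundary layers —
a thin pericellular layer wrapping the monolayer and a thicker unstirred
layer above it — before reaching the bulk supernatant.  Anywhere in the
pericellular layer it can bind surface receptors (EGFR), and bound
complexes are internalized, closing the autocrine loop.  Two interventions
are representable: a soluble decoy antibody that sequesters free ligand,
and a reversible inhibitor of the sheddase that generates the ligand.

Unit conventions (used consistently throughout the package):

========================  =========================================
quantity                  unit
========================  =========================================
time                      minutes
concentration             nM
surface species           molecules per cell
association rate k_on     1/(nM * min)   (0.1 == 1e8 M^-1 min^-1)
dissociation rate k_off   1/min
diffusivity               cm^2/s in configs, cm^2/min internally
volume                    uL in configs, litres internally
ligand release rate       molecules/cell/min
========================  =========================================

The compartment geometry follows standard 96-well culture: a 100 uL well,
a 2 um cell-surface layer (V_S), a 50 um boundary layer over the monolayer
(V_B), and the remaining bulk supernatant (V_BB).  Diffusion-limited
exchange between adjacent compartments i and j is a linear flux
``Delta_ij * (L_i - L_j)`` with ``Delta_ij = D * A / delta_ij`` where
``delta_ij`` is the mean thickness of the adjoining layers.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "AVOGADRO",
    "ConfigError",
    "IntegrationError",
    "UndefinedFractionError",
    "ModelGeometry",
    "LigandSpec",
    "ReceptorSpec",
    "ProteaseSpec",
    "DecoySpec",
    "InhibitorSpec",
    "AutocrineSystem",
    "Trajectory",
    "default_config",
    "build_system",
    "simulate",
    "capture_fraction",
    "free_ligand_fraction",
    "conservation_residual",
]

AVOGADRO = 6.02214076e23

#: default solver settings; molecule-scale states dominate the atol choice
RTOL = 1e-8
ATOL = 1e-12
N_OUTPUT_POINTS = 241


class ConfigError(ValueError):
    """A configuration value is missing, unknown, or inconsistent."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message carries solver diagnostics."""


class UndefinedFractionError(ZeroDivisionError):
    """A ratio (capture fraction, free-ligand fraction) has a zero denominator."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelGeometry:
    """Well geometry and the derived compartment volumes.

    Parameters
    ----------
    well_volume_ul : float
        Total media volume (default 100 uL, a 96-well plate well).
    cell_layer_um : float
        Thickness of the pericellular layer V_S over the monolayer.
    boundary_layer_um : float
        Thickness of the unstirred boundary layer V_B.
    well_area_cm2 : float
        Growth area of the well.
    n_cells : float
        Number of cells in the monolayer.
    """

    well_volume_ul: float = 100.0
    cell_layer_um: float = 2.0
    boundary_layer_um: float = 50.0
    well_area_cm2: float = 0.32
    n_cells: float = 3.0e4

    def __post_init__(self) -> None:
        for name in ("well_volume_ul", "cell_layer_um", "boundary_layer_um",
                     "well_area_cm2"):
            _require(getattr(self, name) > 0, f"geometry.{name} must be > 0")
        _require(self.n_cells > 0,
                 "geometry.n_cells must be > 0 (no cells means no ligand "
                 "source and no capture)")
        _require(self.v_bb_l > 0,
                 "boundary layers exceed the well volume; V_BB would be <= 0")

    # volumes in litres (1 cm^3 = 1e-3 L)
    @property
    def v_s_l(self) -> float:
        return self.well_area_cm2 * self.cell_layer_um * 1e-4 * 1e-3

    @property
    def v_b_l(self) -> float:
        return self.well_area_cm2 * self.boundary_layer_um * 1e-4 * 1e-3

    @property
    def v_bb_l(self) -> float:
        return self.well_volume_ul * 1e-6 - self.v_s_l - self.v_b_l

    @property
    def bulk_thickness_um(self) -> float:
        return self.v_bb_l * 1e3 / self.well_area_cm2 * 1e4

    def transport_l_per_min(self, d_cm2_s: float) -> tuple[float, float]:
        """Transport coefficients (Delta_SB, Delta_BBB) in L/min for a
        species with diffusivity ``d_cm2_s``.

        Delta_ij = D * A / delta_ij with delta_ij the mean of the adjoining
        layer thicknesses, so Delta is linear in D.
        """
        _require(d_cm2_s >= 0, "diffusivity must be >= 0")
        d = d_cm2_s * 60.0  # cm^2/min
        delta_sb_cm = 0.5 * (self.cell_layer_um + self.boundary_layer_um) * 1e-4
        delta_bbb_cm = 0.5 * (self.boundary_layer_um + self.bulk_thickness_um) * 1e-4
        delta_sb = d * self.well_area_cm2 / delta_sb_cm * 1e-3
        delta_bbb = d * self.well_area_cm2 / delta_bbb_cm * 1e-3
        return delta_sb, delta_bbb


def _resolve_binding(kd_nm, kon, koff, what: str) -> tuple[float, float, float]:
    """Resolve (K_D, k_on, k_off) from any consistent pair; reject conflicts."""
    given = {"kd_nM": kd_nm, "kon_per_nM_min": kon, "koff_per_min": koff}
    n = sum(v is not None for v in given.values())
    _require(n >= 2, f"{what}: need at least two of kd_nM/kon_per_nM_min/"
                     "koff_per_min")
    if kd_nm is None:
        kd_nm = koff / kon
    elif koff is None:
        koff = kd_nm * kon
    elif kon is None:
        kon = koff / kd_nm
    elif abs(kd_nm * kon - koff) > 1e-9 * max(abs(koff), 1e-30):
        raise ConfigError(
            f"{what}: kd_nM * kon_per_nM_min = {kd_nm * kon:g} conflicts with "
            f"koff_per_min = {koff:g}")
    for name, v in (("kd_nM", kd_nm), ("kon_per_nM_min", kon),
                    ("koff_per_min", koff)):
        _require(v >= 0, f"{what}.{name} must be >= 0")
    return kd_nm, kon, koff


@dataclass(frozen=True)
class LigandSpec:
    """An autocrine ligand: binding kinetics, transport, and release.

    ``release_rate`` is the lumped shedding flux k_Q * P in
    molecules/cell/min, i.e. what an ELISA accumulation experiment under
    receptor blockade measures.  ``initial_bulk_nM`` allows exogenously
    added ligand (initialized in V_B and V_BB).
    """

    name: str = "ligand"
    kd_nM: float | None = 1.0
    kon_per_nM_min: float | None = 0.1  # 1e8 M^-1 min^-1
    koff_per_min: float | None = None
    d_cm2_s: float = 1.0e-6
    release_rate: float = 10.0
    mw_kda: float = 10.0
    initial_bulk_nM: float = 0.0

    def __post_init__(self) -> None:
        kd, kon, koff = _resolve_binding(
            self.kd_nM, self.kon_per_nM_min, self.koff_per_min,
            f"ligand '{self.name}'")
        object.__setattr__(self, "kd_nM", kd)
        object.__setattr__(self, "kon_per_nM_min", kon)
        object.__setattr__(self, "koff_per_min", koff)
        _require(self.release_rate >= 0,
                 f"ligand '{self.name}'.release_rate must be >= 0")
        _require(self.d_cm2_s >= 0, f"ligand '{self.name}'.d_cm2_s must be >= 0")
        _require(self.mw_kda > 0, f"ligand '{self.name}'.mw_kda must be > 0")
        _require(self.initial_bulk_nM >= 0,
                 f"ligand '{self.name}'.initial_bulk_nM must be >= 0")


@dataclass(frozen=True)
class ReceptorSpec:
    """Surface receptor (EGFR) trafficking parameters.

    With no ligand the receptor count rests at R_ss = q_r / k_t; by default
    q_r is derived from ``r0`` so that R_ss == r0.  ``blockade_fraction``
    emulates a receptor-blocking antibody (mAb225) as instantaneous removal
    of that fraction of receptors and of their synthesis.
    """

    r0: float = 2.0e5
    kt_per_min: float = 0.03       # constitutive internalization
    ke_per_min: float = 0.15       # complex internalization
    qr_per_min: float | None = None
    blockade_fraction: float = 0.0

    def __post_init__(self) -> None:
        _require(self.r0 >= 0, "receptor.r0 must be >= 0")
        _require(self.kt_per_min >= 0, "receptor.kt_per_min must be >= 0")
        _require(self.ke_per_min >= 0, "receptor.ke_per_min must be >= 0")
        if self.qr_per_min is None:
            object.__setattr__(self, "qr_per_min", self.r0 * self.kt_per_min)
        _require(self.qr_per_min >= 0, "receptor.qr_per_min must be >= 0")
        _require(0.0 <= self.blockade_fraction <= 1.0,
                 "receptor.blockade_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ProteaseSpec:
    """Cell-surface sheddase pool driving ligand release.

    Only the product k_Q * P (the ligand's ``release_rate``) enters the
    uninhibited dynamics; the absolute copy number P matters solely for
    inhibitor titration.  Realistic range ~500-50,000 per cell, default
    5000.
    """

    p_per_cell: float = 5000.0

    def __post_init__(self) -> None:
        _require(self.p_per_cell > 0, "protease.p_per_cell must be > 0")


@dataclass(frozen=True)
class DecoySpec:
    """Soluble decoy antibody sequestering free ligand 1:1 reversibly.

    Initialized in the bulk compartments (V_B, V_BB) at ``dose_nM`` and
    equilibrates into the pericellular layer by diffusion.
    """

    kd_nM: float | None = 0.1
    kon_per_nM_min: float | None = 1.0e-3  # 1e6 M^-1 min^-1
    koff_per_min: float | None = None
    d_cm2_s: float = 4.0e-7
    dose_nM: float = 0.0

    def __post_init__(self) -> None:
        kd, kon, koff = _resolve_binding(
            self.kd_nM, self.kon_per_nM_min, self.koff_per_min, "decoy")
        object.__setattr__(self, "kd_nM", kd)
        object.__setattr__(self, "kon_per_nM_min", kon)
        object.__setattr__(self, "koff_per_min", koff)
        _require(self.dose_nM >= 0, "decoy.dose_nM must be >= 0")
        _require(self.d_cm2_s >= 0, "decoy.d_cm2_s must be >= 0")


@dataclass(frozen=True)
class InhibitorSpec:
    """Reversible inhibitor of the sheddase (e.g. a prodomain inhibitor).

    Binds free protease with K_i; shedding flux scales with the free
    protease fraction.  k_off is derived from K_i and k_on, mirroring how
    off-rates are estimated from measured IC50s.
    """

    ki_nM: float | None = 430.0
    kon_per_nM_min: float | None = 1.0e-3
    koff_per_min: float | None = None
    d_cm2_s: float = 1.0e-6
    dose_nM: float = 0.0

    def __post_init__(self) -> None:
        ki, kon, koff = _resolve_binding(
            self.ki_nM, self.kon_per_nM_min, self.koff_per_min, "inhibitor")
        object.__setattr__(self, "ki_nM", ki)
        object.__setattr__(self, "kon_per_nM_min", kon)
        object.__setattr__(self, "koff_per_min", koff)
        _require(self.dose_nM >= 0, "inhibitor.dose_nM must be >= 0")
        _require(self.d_cm2_s >= 0, "inhibitor.d_cm2_s must be >= 0")


@dataclass(frozen=True)
class AutocrineSystem:
    """A fully parameterized cells-in-a-well autocrine system."""

    geometry: ModelGeometry = field(default_factory=ModelGeometry)
    ligands: tuple[LigandSpec, ...] = (LigandSpec(),)
    receptor: ReceptorSpec = field(default_factory=ReceptorSpec)
    proteases: tuple[ProteaseSpec, ...] | None = None
    decoy: DecoySpec | None = None
    inhibitor: InhibitorSpec | None = None

    def __post_init__(self) -> None:
        ligands = tuple(self.ligands)
        _require(len(ligands) >= 1, "at least one ligand is required")
        names = [l.name for l in ligands]
        _require(len(set(names)) == len(names),
                 f"ligand names must be unique, got {names}")
        object.__setattr__(self, "ligands", ligands)
        if self.proteases is None:
            proteases = tuple(ProteaseSpec() for _ in ligands)
        else:
            proteases = tuple(self.proteases)
        _require(len(proteases) == len(ligands),
                 "need exactly one protease spec per ligand")
        object.__setattr__(self, "proteases", proteases)

    def ligand_index(self, name: str) -> int:
        for i, lig in enumerate(self.ligands):
            if lig.name == name:
                return i
        raise KeyError(f"no ligand named {name!r}; have "
                       f"{[l.name for l in self.ligands]}")

    def replace(self, **kwargs) -> "AutocrineSystem":
        return dataclasses.replace(self, **kwargs)

    def with_ligand(self, name: str, **changes) -> "AutocrineSystem":
        """Return a copy with fields of one ligand replaced."""
        i = self.ligand_index(name)
        ligs = list(self.ligands)
        base = {f.name: getattr(ligs[i], f.name)
                for f in dataclasses.fields(LigandSpec)}
        # re-derive the dependent binding constant when one is changed
        if "kd_nM" in changes and "koff_per_min" not in changes:
            base["koff_per_min"] = None
        if "koff_per_min" in changes and "kd_nM" not in changes:
            base["kd_nM"] = None
        if "kon_per_nM_min" in changes and "koff_per_min" not in changes:
            base["koff_per_min"] = None
        base.update(changes)
        ligs[i] = LigandSpec(**base)
        return self.replace(ligands=tuple(ligs))


# ---------------------------------------------------------------------------
# configuration plumbing
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """The shipped 12Z-like default configuration as a plain dict.

    Two ligands: a high-affinity HB-EGF-like species (K_D = 1 nM) and a
    low-affinity AREG-like species (K_D = 100 nM), with release rates on
    the scale measured by 24-h supernatant accumulation under receptor
    blockade.  Loaded from the annotated ``defaults.yaml`` shipped with
    the package.
    """
    import importlib.resources

    import yaml

    text = (importlib.resources.files("autoloop") / "defaults.yaml").read_text()
    cfg = yaml.safe_load(text)
    for key in ("geometry", "receptor", "protease"):
        cfg[key] = {k: float(v) if k != "name" else v
                    for k, v in cfg[key].items()}
    return cfg


_SECTION_TYPES = {
    "geometry": ModelGeometry,
    "receptor": ReceptorSpec,
    "protease": ProteaseSpec,
    "decoy": DecoySpec,
    "inhibitor": InhibitorSpec,
}


def _build_section(cls, section: dict, what: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    _require(not unknown,
             f"unknown key(s) {sorted(unknown)} in section '{what}'; "
             f"valid keys: {sorted(valid)}")
    return cls(**section)


def build_system(config: dict | None = None) -> AutocrineSystem:
    """Assemble a validated :class:`AutocrineSystem` from a nested config.

    ``config`` uses sections ``geometry``, ``receptor``, ``protease``,
    ``ligands`` (list), ``decoy``, ``inhibitor``; any omitted field takes
    the documented default, unknown keys are rejected.  ``protease`` may
    also be a list (one entry per ligand).
    """
    config = copy.deepcopy(config) if config else {}
    _require(isinstance(config, dict), "config must be a mapping")
    known = set(_SECTION_TYPES) | {"ligands"}
    unknown = set(config) - known
    _require(not unknown,
             f"unknown config section(s) {sorted(unknown)}; "
             f"valid sections: {sorted(known)}")

    geometry = _build_section(ModelGeometry, config.get("geometry", {}),
                              "geometry")
    receptor = _build_section(ReceptorSpec, config.get("receptor", {}),
                              "receptor")
    lig_cfgs = config.get("ligands", default_config()["ligands"])
    _require(isinstance(lig_cfgs, (list, tuple)) and lig_cfgs,
             "'ligands' must be a non-empty list")
    ligands = tuple(_build_section(LigandSpec, c, f"ligands[{i}]")
                    for i, c in enumerate(lig_cfgs))
    prot_cfg = config.get("protease", {})
    if isinstance(prot_cfg, (list, tuple)):
        _require(len(prot_cfg) == len(ligands),
                 "protease list length must match number of ligands")
        proteases = tuple(_build_section(ProteaseSpec, c, f"protease[{i}]")
                          for i, c in enumerate(prot_cfg))
    else:
        one = _build_section(ProteaseSpec, prot_cfg, "protease")
        proteases = tuple(one for _ in ligands)
    decoy = (_build_section(DecoySpec, config["decoy"], "decoy")
             if "decoy" in config else None)
    inhibitor = (_build_section(InhibitorSpec, config["inhibitor"], "inhibitor")
                 if "inhibitor" in config else None)
    return AutocrineSystem(geometry=geometry, ligands=ligands,
                           receptor=receptor, proteases=proteases,
                           decoy=decoy, inhibitor=inhibitor)


def default_system() -> AutocrineSystem:
    """The shipped two-ligand 12Z-like default system."""
    return build_system(default_config())


# ---------------------------------------------------------------------------
# state indexing and right-hand side
# ---------------------------------------------------------------------------

class _Layout:
    """Index map for the flat ODE state vector."""

    def __init__(self, system: AutocrineSystem):
        n_lig = len(system.ligands)
        self.n_lig = n_lig
        self.has_decoy = system.decoy is not None
        self.has_inhibitor = system.inhibitor is not None
        i = 0
        self.i_r = i; i += 1
        self.i_c = slice(i, i + n_lig); i += n_lig
        # free ligand, 3 compartments per ligand (row-major: ligand, comp)
        self.i_l = slice(i, i + 3 * n_lig); i += 3 * n_lig
        self.i_rel = slice(i, i + n_lig); i += n_lig
        self.i_int = slice(i, i + n_lig); i += n_lig
        if self.has_decoy:
            self.i_a = slice(i, i + 3); i += 3
            self.i_la = slice(i, i + 3 * n_lig); i += 3 * n_lig
        if self.has_inhibitor:
            self.i_inh = slice(i, i + 3); i += 3
            self.i_pi = i; i += 1
        self.n = i


def _rhs_factory(system: AutocrineSystem, layout: _Layout):
    geo = system.geometry
    rec = system.receptor
    n_lig = layout.n_lig
    vols = np.array([geo.v_s_l, geo.v_b_l, geo.v_bb_l])
    # molecules/cell -> nM in compartment x: m * conv[x]
    conv = geo.n_cells / (AVOGADRO * vols) * 1e9
    block = 1.0 - rec.blockade_fraction
    qr = rec.qr_per_min * block
    kt, ke = rec.kt_per_min, rec.ke_per_min

    kon = np.array([l.kon_per_nM_min for l in system.ligands])
    koff = np.array([l.koff_per_min for l in system.ligands])
    q_rel = np.array([l.release_rate for l in system.ligands])
    delta = np.array([geo.transport_l_per_min(l.d_cm2_s)
                      for l in system.ligands])  # (n_lig, 2)

    if layout.has_decoy:
        ab = system.decoy
        delta_ab = np.array(geo.transport_l_per_min(ab.d_cm2_s))
    if layout.has_inhibitor:
        inh = system.inhibitor
        p_tot = np.array([p.p_per_cell for p in system.proteases])
        # one protease pool per ligand is titrated identically; model the
        # first pool explicitly (pools share P and K_i by construction)
        p0 = p_tot[0]
        delta_inh = np.array(geo.transport_l_per_min(inh.d_cm2_s))

    def diffuse(c3, d2):
        """Net d(conc)/dt from inter-compartment diffusion for one species."""
        f_sb = d2[0] * (c3[0] - c3[1])    # mol-flux S->B (per nM*L/min)
        f_bbb = d2[1] * (c3[1] - c3[2])
        return np.array([-f_sb / vols[0],
                         (f_sb - f_bbb) / vols[1],
                         f_bbb / vols[2]])

    def rhs(t, y):
        dy = np.zeros_like(y)
        r = y[layout.i_r]
        c = y[layout.i_c]
        lig = y[layout.i_l].reshape(n_lig, 3)

        free_frac = 1.0
        if layout.has_inhibitor:
            pi = y[layout.i_pi]
            free_frac = max(p0 - pi, 0.0) / p0

        bind = kon * lig[:, 0] * r        # molecules/cell/min, per ligand
        unbind = koff * c
        dy[layout.i_r] = qr - kt * r - bind.sum() + unbind.sum()
        dy[layout.i_c] = bind - unbind - ke * c
        dy[layout.i_rel] = q_rel * free_frac
        dy[layout.i_int] = ke * c

        dlig = np.empty((n_lig, 3))
        for i in range(n_lig):
            dlig[i] = diffuse(lig[i], delta[i])
        dlig[:, 0] += (q_rel * free_frac - bind + unbind) * conv[0]

        if layout.has_decoy:
            a = y[layout.i_a]
            la = y[layout.i_la].reshape(n_lig, 3)
            b = ab.kon_per_nM_min * lig * a[None, :] - ab.koff_per_min * la
            dla = np.empty((n_lig, 3))
            for i in range(n_lig):
                dla[i] = diffuse(la[i], delta_ab) + b[i]
            da = diffuse(a, delta_ab) - b.sum(axis=0)
            dy[layout.i_a] = da
            dy[layout.i_la] = dla.ravel()
            dlig -= b

        if layout.has_inhibitor:
            ii = y[layout.i_inh]
            pi = y[layout.i_pi]
            b_i = inh.kon_per_nM_min * ii[0] * (p0 - pi) \
                - inh.koff_per_min * pi          # molecules/cell/min
            dii = diffuse(ii, delta_inh)
            dii[0] -= b_i * conv[0]
            dy[layout.i_inh] = dii
            dy[layout.i_pi] = b_i

        dy[layout.i_l] = dlig.ravel()
        return dy

    return rhs


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Solution of a 24-h (by default) autocrine simulation.

    Surface species are in molecules/cell, compartment species in nM, time
    in minutes.  ``states`` is a (n_states, n_times) array addressed
    through the helper accessors.
    """

    system: AutocrineSystem
    t_min: np.ndarray
    states: np.ndarray
    rtol: float
    atol: float
    success: bool
    solver_message: str

    def __post_init__(self) -> None:
        self._layout = _Layout(self.system)

    # -- accessors ----------------------------------------------------------
    def receptors(self) -> np.ndarray:
        return self.states[self._layout.i_r]

    def complexes(self, ligand: str | None = None) -> np.ndarray:
        """Ligand-receptor complexes per cell (summed over ligands if
        ``ligand`` is None)."""
        c = self.states[self._layout.i_c]
        if ligand is None:
            return c.sum(axis=0)
        return c[self.system.ligand_index(ligand)]

    def free_ligand_nM(self, ligand: str) -> np.ndarray:
        """Free ligand concentration, shape (3 compartments, n_times)."""
        i = self.system.ligand_index(ligand)
        n_lig = self._layout.n_lig
        lig = self.states[self._layout.i_l].reshape(n_lig, 3, -1)
        return lig[i]

    def decoy_complex_nM(self, ligand: str) -> np.ndarray:
        if not self._layout.has_decoy:
            return np.zeros((3, len(self.t_min)))
        i = self.system.ligand_index(ligand)
        la = self.states[self._layout.i_la].reshape(self._layout.n_lig, 3, -1)
        return la[i]

    def cumulative_released(self, ligand: str) -> np.ndarray:
        i = self.system.ligand_index(ligand)
        return self.states[self._layout.i_rel][i]

    def cumulative_internalized(self, ligand: str) -> np.ndarray:
        i = self.system.ligand_index(ligand)
        return self.states[self._layout.i_int][i]

    def free_ligand_molecules_per_cell(self, ligand: str) -> np.ndarray:
        """Total free ligand over all compartments, as molecules/cell."""
        geo = self.system.geometry
        vols = np.array([geo.v_s_l, geo.v_b_l, geo.v_bb_l])
        conc = self.free_ligand_nM(ligand)  # (3, nt)
        return (conc * vols[:, None]).sum(axis=0) * 1e-9 * AVOGADRO / geo.n_cells

    def decoy_complex_molecules_per_cell(self, ligand: str) -> np.ndarray:
        geo = self.system.geometry
        vols = np.array([geo.v_s_l, geo.v_b_l, geo.v_bb_l])
        conc = self.decoy_complex_nM(ligand)
        return (conc * vols[:, None]).sum(axis=0) * 1e-9 * AVOGADRO / geo.n_cells

    def to_frame(self):
        """Tidy DataFrame (time_min, species, compartment, value, units)."""
        import pandas as pd

        rows = []
        comp_names = ("S", "B", "BB")
        t = self.t_min
        rows.append(pd.DataFrame({"time_min": t, "species": "receptor",
                                  "compartment": "surface",
                                  "value": self.receptors(),
                                  "units": "molecules/cell"}))
        for lig in self.system.ligands:
            rows.append(pd.DataFrame({
                "time_min": t, "species": f"complex:{lig.name}",
                "compartment": "surface",
                "value": self.complexes(lig.name),
                "units": "molecules/cell"}))
            conc = self.free_ligand_nM(lig.name)
            for k, comp in enumerate(comp_names):
                rows.append(pd.DataFrame({
                    "time_min": t, "species": f"ligand:{lig.name}",
                    "compartment": comp, "value": conc[k], "units": "nM"}))
            for name, arr in (("released", self.cumulative_released(lig.name)),
                              ("internalized",
                               self.cumulative_internalized(lig.name))):
                rows.append(pd.DataFrame({
                    "time_min": t, "species": f"{name}:{lig.name}",
                    "compartment": "cumulative", "value": arr,
                    "units": "molecules/cell"}))
        return pd.concat(rows, ignore_index=True)


def _initial_state(system: AutocrineSystem, layout: _Layout) -> np.ndarray:
    y0 = np.zeros(layout.n)
    block = 1.0 - system.receptor.blockade_fraction
    y0[layout.i_r] = system.receptor.r0 * block
    lig0 = np.zeros((layout.n_lig, 3))
    for i, lig in enumerate(system.ligands):
        if lig.initial_bulk_nM:
            lig0[i, 1] = lig0[i, 2] = lig.initial_bulk_nM
    y0[layout.i_l] = lig0.ravel()
    if layout.has_decoy:
        a0 = np.zeros(3)
        a0[1] = a0[2] = system.decoy.dose_nM  # bulk initialization
        y0[layout.i_a] = a0
    if layout.has_inhibitor:
        i0 = np.zeros(3)
        i0[1] = i0[2] = system.inhibitor.dose_nM
        y0[layout.i_inh] = i0
    return y0


def simulate(system: AutocrineSystem, duration_min: float = 1440.0,
             rtol: float = RTOL, atol: float = ATOL,
             n_points: int = N_OUTPUT_POINTS) -> Trajectory:
    """Integrate the system over ``duration_min`` minutes (default 24 h).

    Uses a stiff solver (LSODA) at tight tolerances; the returned
    trajectory satisfies per-ligand mass balance (see
    :func:`conservation_residual`) to ~solver precision.

    Raises
    ------
    IntegrationError
        If the solver fails or produces non-finite state.
    """
    _require(duration_min > 0, "duration must be > 0")
    layout = _Layout(system)
    rhs = _rhs_factory(system, layout)
    y0 = _initial_state(system, layout)
    t_eval = np.linspace(0.0, duration_min, n_points)
    sol = solve_ivp(rhs, (0.0, duration_min), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed (rtol={rtol:g}, atol={atol:g}): "
            f"{sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError("non-finite state encountered in solution")
    return Trajectory(system=system, t_min=sol.t, states=sol.y,
                      rtol=rtol, atol=atol, success=True,
                      solver_message=sol.message)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def capture_fraction(trajectory: Trajectory, ligand: str | None = None) -> float:
    """Cumulative fraction of released ligand internalized via receptors.

    ``cumulative_internalized / cumulative_released`` at the final time;
    the classic localization readout: ~1 for high-affinity ligands that
    are recaptured before escaping, small for low-affinity ligands that
    accumulate in the bulk supernatant.

    Raises
    ------
    UndefinedFractionError
        If nothing was released (the ratio is undefined, not zero).
    """
    if ligand is None:
        ligand = trajectory.system.ligands[0].name
    rel = trajectory.cumulative_released(ligand)[-1]
    if rel <= 0:
        raise UndefinedFractionError(
            f"no ligand '{ligand}' released; capture fraction undefined")
    frac = trajectory.cumulative_internalized(ligand)[-1] / rel
    return float(min(max(frac, 0.0), 1.0))


def free_ligand_fraction(system: AutocrineSystem, ligand: str | None = None,
                         duration_min: float = 1440.0) -> float:
    """Fraction of bulk free ligand from a paired +/- receptor-blockade run.

    Emulates the supernatant-accumulation experiment: the ratio of total
    free supernatant ligand after ``duration_min`` without receptor
    blockade to that with full blockade.  Approximately equals
    ``1 - capture_fraction``; the two differ by ligand still in transit or
    receptor-bound at harvest.
    """
    if ligand is None:
        ligand = system.ligands[0].name
    blocked = simulate(system.replace(
        receptor=dataclasses.replace(system.receptor, blockade_fraction=1.0)),
        duration_min)
    unblocked = simulate(system.replace(
        receptor=dataclasses.replace(system.receptor, blockade_fraction=0.0)),
        duration_min)
    denom = blocked.free_ligand_molecules_per_cell(ligand)[-1]
    if denom <= 0:
        raise UndefinedFractionError(
            f"no free ligand '{ligand}' accumulated under blockade; "
            "fraction undefined")
    num = unblocked.free_ligand_molecules_per_cell(ligand)[-1]
    return float(min(max(num / denom, 0.0), 1.0))


def conservation_residual(trajectory: Trajectory) -> float:
    """Worst-case relative mass-balance violation over ligands and time.

    For each ligand, released + initial must equal free (all compartments)
    + antibody-bound + receptor-bound + internalized at every output time;
    returns max |imbalance| / max(released + initial, 1 molecule/cell).
    """
    worst = 0.0
    geo = trajectory.system.geometry
    for lig in trajectory.system.ligands:
        init = (lig.initial_bulk_nM * (geo.v_b_l + geo.v_bb_l)
                * 1e-9 * AVOGADRO / geo.n_cells)
        supply = trajectory.cumulative_released(lig.name) + init
        inventory = (trajectory.free_ligand_molecules_per_cell(lig.name)
                     + trajectory.decoy_complex_molecules_per_cell(lig.name)
                     + trajectory.complexes(lig.name)
                     + trajectory.cumulative_internalized(lig.name))
        scale = max(float(np.max(supply)), 1.0)
        worst = max(worst, float(np.max(np.abs(supply - inventory))) / scale)
    return worst
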