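"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of (config, seed) and returns its
dataset together with a :class:`GroundTruth` sidecar recording the latent
quantities it was built from, so recovery tests read truth only from the
sidecar.  The default panel mirrors a cue-signal-response experiment:
8 growth-factor/cytokine cues x +/- receptor blockade = 16 conditions,
7 FRET substrates with 4 replicates at 5 timepoints, 3 ELISA replicates.

Noise models are conventional for the assay class: additive Gaussian for
fluorescence (scaled to the signal range), multiplicative log-normal
(CV ~10%) for immunoassays and cell counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .csr_pipeline import FretPanel, SignatureMatrix
from .enzyme_kinetics import InhibitionAssay, _hyperbolic, _morrison
from .model_core import AutocrineSystem, simulate, capture_fraction
from .parameterization import SupernatantMeasurement

__all__ = [
    "GroundTruth",
    "DEFAULT_CUES",
    "default_conditions",
    "default_signature",
    "default_coupling",
    "gen_activities",
    "gen_fret_panel",
    "gen_shedding_panel",
    "gen_capture_experiment",
    "gen_dose_response",
]

DEFAULT_CUES = ("untreated", "EGF", "TGFa", "HB-EGF", "AREG", "NRG1b",
                "BTC", "TNFa")
PROTEASES = ("ADAM8", "ADAM10", "ADAM12", "ADAM17")
SUBSTRATES = tuple(f"FRET-{i}" for i in range(1, 8))
ANALYTES = ("HB-EGF", "AREG", "TGFa", "TNFR1", "HER2", "MET")


def default_conditions() -> list[str]:
    """16 condition labels: 8 cues x (+/- receptor blockade)."""
    return [f"{cue}{suffix}" for suffix in ("", "+mAb")
            for cue in DEFAULT_CUES]


@dataclass
class GroundTruth:
    """Latent quantities behind a generated dataset.

    Serialized next to every dataset; regeneration from (seed, config) is
    bit-identical, and all round-trip tests read truth from here only.
    """

    seed: int
    activities: dict | None = None          # condition -> protease -> value
    coupling: dict | None = None            # protease -> analyte -> value
    system_params: dict | None = None
    noise_model: str = "none"
    noise_scale: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def default_signature() -> SignatureMatrix:
    """A documented, synthetic 7-substrate x 4-protease signature.

    Catalytic efficiencies (arbitrary but fixed units) chosen so that
    every protease has at least one preferred substrate and columns are
    well separated (condition number ~ a few), the regime in which FRET
    deconvolution is informative.  This is a stand-in constructed for
    testing, not a published specificity table.
    """
    values = np.array([
        # ADAM8  ADAM10 ADAM12 ADAM17
        [0.9, 0.1, 0.0, 0.2],   # FRET-1
        [0.1, 1.2, 0.1, 0.0],   # FRET-2
        [0.0, 0.2, 1.0, 0.1],   # FRET-3
        [0.2, 0.0, 0.1, 1.1],   # FRET-4
        [0.5, 0.6, 0.0, 0.4],   # FRET-5
        [0.0, 0.4, 0.7, 0.6],   # FRET-6
        [0.3, 0.0, 0.5, 0.8],   # FRET-7
    ])
    return SignatureMatrix(pd.DataFrame(values, index=list(SUBSTRATES),
                                        columns=list(PROTEASES)))


def default_coupling() -> pd.DataFrame:
    """Synthetic protease -> analyte shedding couplings (proteases x
    analytes), with the attributions the assay is expected to resolve:
    ADAM12 dominates HB-EGF shedding, ADAM17 dominates AREG/TGFa/TNFR1,
    ADAM10 dominates the receptor ectodomains."""
    values = np.array([
        # HB-EGF AREG  TGFa  TNFR1 HER2  MET
        [0.05, 0.05, 0.00, 0.40, 0.05, 0.00],   # ADAM8
        [0.10, 0.20, 0.15, 0.10, 1.00, 0.90],   # ADAM10
        [1.00, 0.05, 0.10, 0.00, 0.10, 0.05],   # ADAM12
        [0.15, 0.90, 0.80, 0.90, 0.15, 0.10],   # ADAM17
    ])
    return pd.DataFrame(values, index=list(PROTEASES),
                        columns=list(ANALYTES))


def gen_activities(seed: int, conditions=None,
                   low: float = 0.2, high: float = 2.0) -> pd.DataFrame:
    """Latent protease activities per condition, uniform on [low, high]
    (concentration-equivalent units); cue-driven variation across the
    panel is what the correlation analysis exploits."""
    conditions = list(conditions) if conditions is not None \
        else default_conditions()
    rng = np.random.default_rng(seed)
    act = rng.uniform(low, high, size=(len(conditions), len(PROTEASES)))
    return pd.DataFrame(act, index=conditions, columns=list(PROTEASES))


def _truth_activities(activities: pd.DataFrame) -> dict:
    return {c: {p: float(activities.loc[c, p]) for p in activities.columns}
            for c in activities.index}


def gen_fret_panel(activities: pd.DataFrame | GroundTruth,
                   signature: SignatureMatrix | None = None,
                   seed: int = 0, noise_scale: float = 0.05,
                   n_replicates: int = 4,
                   timepoints_min=(0.0, 45.0, 90.0, 135.0, 180.0),
                   offset: float = 100.0
                   ) -> tuple[FretPanel, GroundTruth]:
    """FRET fluorescence panel with linear-in-time cleavage.

    fluorescence(t) = offset + (signature @ activities) * t + eps,
    eps ~ N(0, (noise_scale * signal_range)^2), signal_range being the
    largest fluorescence excursion in the noiseless panel.
    """
    if isinstance(activities, GroundTruth):
        activities = pd.DataFrame(activities.activities).T
    if signature is None:
        signature = default_signature()
    if (activities.values < 0).any():
        raise ValueError("latent activities must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints_min, dtype=float)
    rates = activities.values @ signature.table.values.T  # cond x substrate
    clean = offset + rates[:, :, None, None] * t[None, None, None, :]
    clean = np.broadcast_to(
        clean, (len(activities), len(signature.substrates), n_replicates,
                len(t))).copy()
    signal_range = float(np.ptp(clean)) or 1.0
    noisy = clean + rng.normal(0.0, noise_scale * signal_range, clean.shape)
    panel = FretPanel(conditions=list(activities.index),
                      substrates=signature.substrates,
                      timepoints_min=t, fluorescence=noisy)
    truth = GroundTruth(seed=seed, activities=_truth_activities(activities),
                        noise_model="additive-gaussian",
                        noise_scale=noise_scale,
                        extras={"offset": offset,
                                "true_rates": rates.tolist()})
    return panel, truth


def gen_shedding_panel(activities: pd.DataFrame, coupling=None, seed: int = 0,
                       noise_cv: float = 0.10, baseline: float = 20.0,
                       scale: float = 100.0, n_replicates: int = 3,
                       mean_cells: float = 1e5
                       ) -> tuple[dict, GroundTruth]:
    """ELISA-style supernatant panel driven linearly by protease activity.

    response = scale * (coupling^T @ activity) + baseline, with
    multiplicative log-normal noise (CV ``noise_cv``) per replicate; the
    matched metalloproteinase-inhibitor background panel carries baseline
    + noise only.  Cell counts are log-normal around ``mean_cells``.

    Returns a dict with DataFrames ``raw`` (replicate-mean), ``background``,
    Series ``cell_counts``, plus per-replicate arrays in ``replicates``.
    """
    if coupling is None:
        coupling = default_coupling()
    rng = np.random.default_rng(seed)
    conditions = list(activities.index)
    analytes = list(coupling.columns)
    clean = scale * (activities.values @ coupling.values) + baseline
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    mu = -sigma ** 2 / 2.0  # unit-mean log-normal factors

    def noisy(base, shape):
        return base * rng.lognormal(mu, sigma, shape)

    reps = noisy(clean[:, :, None], (*clean.shape, n_replicates))
    bg_reps = noisy(baseline, (len(conditions), len(analytes), n_replicates))
    cells = mean_cells * rng.lognormal(mu, sigma, len(conditions))
    raw = pd.DataFrame(reps.mean(axis=2), index=conditions, columns=analytes)
    background = pd.DataFrame(bg_reps.mean(axis=2), index=conditions,
                              columns=analytes)
    cell_counts = pd.Series(cells, index=conditions)
    truth = GroundTruth(
        seed=seed, activities=_truth_activities(activities),
        coupling={p: {a: float(coupling.loc[p, a]) for a in analytes}
                  for p in coupling.index},
        noise_model="multiplicative-lognormal", noise_scale=noise_cv,
        extras={"baseline": baseline, "scale": scale,
                "mean_cells": mean_cells})
    data = {"raw": raw, "background": background, "cell_counts": cell_counts,
            "replicates": reps, "background_replicates": bg_reps}
    return data, truth


def gen_capture_experiment(system: AutocrineSystem, ligand: str | None = None,
                           noise_cv: float = 0.0, seed: int = 0,
                           duration_min: float = 1440.0
                           ) -> tuple[dict, GroundTruth]:
    """Paired +/- receptor-blockade supernatant measurements from the ODE
    model, in immunoassay units (ng/mL) with multiplicative noise.

    The BB94-style background is emulated as zero shedding, so the
    generated backgrounds are 0 and the net concentrations equal the
    modeled free-ligand accumulations (plus noise).
    """
    import dataclasses as _dc

    if ligand is None:
        ligand = system.ligands[0].name
    lig = system.ligands[system.ligand_index(ligand)]
    rng = np.random.default_rng(seed)
    out = {}
    truth_extras = {}
    for label, blockade in (("unblocked", 0.0), ("blocked", 1.0)):
        sys_i = system.replace(receptor=_dc.replace(
            system.receptor, blockade_fraction=blockade))
        traj = simulate(sys_i, duration_min)
        molecules = traj.free_ligand_molecules_per_cell(ligand)[-1] \
            * system.geometry.n_cells
        ng = molecules / 6.02214076e23 * lig.mw_kda * 1e3 * 1e9
        volume_ml = system.geometry.well_volume_ul * 1e-3
        conc = ng / volume_ml
        truth_extras[f"true_{label}_ng_ml"] = conc
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv ** 2))
            conc = float(conc * rng.lognormal(-sigma ** 2 / 2, sigma))
        out[label] = SupernatantMeasurement(
            concentration_ng_ml=conc, background_ng_ml=0.0,
            volume_ml=volume_ml, viable_cells=system.geometry.n_cells,
            duration_min=duration_min, blockade=(blockade == 1.0),
            analyte=ligand)
    unblocked_traj = simulate(system, duration_min)
    truth = GroundTruth(
        seed=seed,
        system_params={"ligand": ligand, "kd_nM": lig.kd_nM,
                       "release_rate": lig.release_rate},
        noise_model="multiplicative-lognormal" if noise_cv else "none",
        noise_scale=noise_cv,
        extras={**truth_extras,
                "true_capture_fraction":
                    capture_fraction(unblocked_traj, ligand)})
    return out, truth


def gen_dose_response(ki_nM: float, model: str = "hyperbolic",
                      enzyme: str = "ADAM12", enzyme_conc_nM: float = 5.0,
                      substrate_conc_uM: float = 15.0, top_dose_nM: float = 1e4,
                      n_doses: int = 6, dilution: float = 3.0,
                      v0: float = 1.0, noise_cv: float = 0.0,
                      n_replicates: int = 2, seed: int = 0
                      ) -> tuple[InhibitionAssay, GroundTruth]:
    """Inhibitor dilution-series assay from a known potency.

    ``model`` selects the generating curve: "hyperbolic" treats ``ki_nM``
    as the IC50 of the one-site hyperbola; "tight-binding" uses the
    Morrison quadratic with K_app = ``ki_nM`` at the stated enzyme
    concentration.  Doses are a ``dilution``-fold series down from
    ``top_dose_nM`` plus an uninhibited 0-dose anchor; noise is
    multiplicative log-normal per replicate.
    """
    if model not in ("hyperbolic", "tight-binding"):
        raise ValueError("model must be 'hyperbolic' or 'tight-binding'")
    rng = np.random.default_rng(seed)
    doses = top_dose_nM / dilution ** np.arange(n_doses)
    doses = np.concatenate([[0.0], doses[::-1]])
    if model == "hyperbolic":
        clean = _hyperbolic(doses, v0, ki_nM)
    else:
        clean = _morrison(doses, v0, ki_nM, enzyme_conc_nM)
    rates = np.broadcast_to(clean[:, None],
                            (len(doses), n_replicates)).copy()
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        rates = rates * rng.lognormal(-sigma ** 2 / 2, sigma, rates.shape)
    assay = InhibitionAssay(enzyme=enzyme, doses_nM=doses, rates=rates,
                            enzyme_conc_nM=enzyme_conc_nM,
                            substrate_conc_uM=substrate_conc_uM)
    truth = GroundTruth(
        seed=seed,
        system_params={"ki_nM": ki_nM, "model": model,
                       "enzyme_conc_nM": enzyme_conc_nM, "v0": v0},
        noise_model="multiplicative-lognormal" if noise_cv else "none",
        noise_scale=noise_cv)
    return assay, truth
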