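"""Turn supernatant immunoassays and receptor staining into model rates.

The experimental workflow this mirrors: cells are cultured 24 h with or
without a receptor-blocking antibody (mAb225) and with a broad-spectrum
metalloproteinase inhibitor (BB94) as the shedding-negative background;
supernatant ligand is quantified by ELISA and normalized to viable cell
counts.  Under blockade nothing is recaptured, so the background-corrected
accumulation divided by cells and time is the lumped release rate k_Q*P in
molecules/cell/min.  The unblocked/blocked concentration ratio is the
experimental fraction of bulk free ligand (the complement of capture).
Receptor numbers come from bead-calibrated flow cytometry through a
standard curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .model_core import (
    AVOGADRO,
    AutocrineSystem,
    ConfigError,
    build_system,
    default_config,
    free_ligand_fraction,
)

__all__ = [
    "SupernatantMeasurement",
    "RateEstimate",
    "CaptureRatio",
    "CalibrationCurve",
    "ReceptorCount",
    "CalibrationOutcome",
    "release_rate_from_supernatant",
    "capture_ratio",
    "receptor_count_from_calibration",
    "calibrate_system",
]


@dataclass(frozen=True)
class SupernatantMeasurement:
    """One 24-h supernatant accumulation measurement.

    ``background_ng_ml`` is the matched metalloproteinase-inhibitor
    (BB94-style) negative control; ``blockade`` records whether receptor
    capture was switched off (mAb225) during accumulation.
    """

    concentration_ng_ml: float
    volume_ml: float
    viable_cells: float
    duration_min: float = 1440.0
    background_ng_ml: float | None = None
    blockade: bool = True
    analyte: str = "ligand"

    def __post_init__(self) -> None:
        if self.concentration_ng_ml < 0:
            raise ConfigError("concentration must be >= 0")
        if self.background_ng_ml is not None and self.background_ng_ml < 0:
            raise ConfigError("background must be >= 0")
        if self.volume_ml <= 0:
            raise ConfigError("volume must be > 0")
        if self.viable_cells <= 0:
            raise ConfigError("viable_cells must be > 0")
        if self.duration_min <= 0:
            raise ConfigError("duration must be > 0")

    @property
    def net_ng_ml(self) -> float:
        if self.background_ng_ml is None:
            raise ConfigError(
                "measurement has no negative-control background; "
                "background correction is mandatory")
        return self.concentration_ng_ml - self.background_ng_ml


@dataclass(frozen=True)
class RateEstimate:
    """A release-rate estimate in molecules/cell/min with QC flags."""

    rate: float
    clamped: bool = False
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class CaptureRatio:
    """Experimental bulk-free-ligand fraction (unblocked/blocked)."""

    fraction: float
    clipped: bool = False
    warnings: tuple[str, ...] = ()


def release_rate_from_supernatant(m: SupernatantMeasurement,
                                  mw_kda: float) -> RateEstimate:
    """Lumped shedding rate k_Q*P from a blockade accumulation experiment.

    rate = max(0, conc - background) * volume * N_A / (MW * cells * t).

    A measurement taken without receptor blockade still yields a number,
    but it underestimates release by the captured share; the result then
    carries a capture-confound warning.
    """
    if mw_kda <= 0:
        raise ConfigError("molecular weight must be > 0")
    net = m.net_ng_ml  # raises if background missing
    warnings = ()
    if not m.blockade:
        warnings = ("measurement taken without receptor blockade; "
                    "receptor capture confounds the release-rate estimate",)
    clamped = net < 0
    net = max(net, 0.0)
    molecules = net * 1e-9 * m.volume_ml / (mw_kda * 1e3) * AVOGADRO
    rate = molecules / (m.viable_cells * m.duration_min)
    return RateEstimate(rate=rate, clamped=clamped, warnings=warnings)


def capture_ratio(unblocked: SupernatantMeasurement,
                  blocked: SupernatantMeasurement) -> CaptureRatio:
    """Experimental fraction of bulk free ligand, net(-mAb)/net(+mAb).

    Both arms are background-corrected per-arm.  Ratios above 1 (possible
    with measurement noise) are clipped to 1 with a flag.
    """
    net_b = blocked.net_ng_ml
    net_u = unblocked.net_ng_ml
    if net_b <= 0:
        raise ConfigError("blocked-arm net concentration must be > 0 to "
                          "form a capture ratio")
    warnings = ()
    if not blocked.blockade:
        warnings += ("'blocked' arm is not flagged as blockaded",)
    if unblocked.blockade:
        warnings += ("'unblocked' arm is flagged as blockaded",)
    frac = max(net_u, 0.0) / net_b
    clipped = frac > 1.0
    return CaptureRatio(fraction=min(frac, 1.0), clipped=clipped,
                        warnings=warnings)


# ---------------------------------------------------------------------------
# receptor-number calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationCurve:
    """Bead standard curve: (signal, known antibody-binding capacity) pairs.

    The inverse mapping is piecewise linear through the calibrators (so a
    signal at a calibration point maps to that point's quantity exactly);
    the stored least-squares line is a linearity diagnostic.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(s), float(q)) for s, q in self.points)
        if len(pts) < 2:
            raise ConfigError("calibration needs >= 2 points")
        qs = [q for _, q in pts]
        ss = [s for s, _ in pts]
        if any(q1 <= q0 for q0, q1 in zip(qs, qs[1:])):
            raise ConfigError("calibrator quantities must be strictly "
                              "increasing")
        if any(s1 <= s0 for s0, s1 in zip(ss, ss[1:])):
            raise ConfigError("calibration curve is non-monotone in signal")
        object.__setattr__(self, "points", pts)

    @property
    def signals(self) -> np.ndarray:
        return np.array([s for s, _ in self.points])

    @property
    def quantities(self) -> np.ndarray:
        return np.array([q for _, q in self.points])

    def linear_fit(self) -> tuple[float, float, float]:
        """(slope, intercept, R^2) of signal ~ quantity."""
        q, s = self.quantities, self.signals
        slope, intercept = np.polyfit(q, s, 1)
        pred = slope * q + intercept
        ss_res = float(np.sum((s - pred) ** 2))
        ss_tot = float(np.sum((s - s.mean()) ** 2))
        return float(slope), float(intercept), 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class ReceptorCount:
    receptors_per_cell: float
    extrapolated: bool = False


def receptor_count_from_calibration(signal: float,
                                    curve: CalibrationCurve) -> ReceptorCount:
    """Map a fluorescence signal to receptors/cell through the bead curve.

    Signals outside the calibrated range are linearly extrapolated from
    the nearest segment and flagged; results clamp at zero.
    """
    s, q = curve.signals, curve.quantities
    extrapolated = signal < s[0] or signal > s[-1]
    if extrapolated:
        seg = (0, 1) if signal < s[0] else (len(s) - 2, len(s) - 1)
        slope = (q[seg[1]] - q[seg[0]]) / (s[seg[1]] - s[seg[0]])
        value = q[seg[0]] + slope * (signal - s[seg[0]])
    else:
        value = float(np.interp(signal, s, q))
    return ReceptorCount(receptors_per_cell=max(value, 0.0),
                         extrapolated=extrapolated)


# ---------------------------------------------------------------------------
# wiring measurements into a model system
# ---------------------------------------------------------------------------

@dataclass
class CalibrationOutcome:
    """Result of calibrating the model against measured observables."""

    system: AutocrineSystem
    fitted_kd_nM: dict = field(default_factory=dict)
    achieved_free_fraction: dict = field(default_factory=dict)
    boundary_flags: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)


_LOG_KD_BOUNDS = (-1.0, 4.0)  # 0.1 nM .. 10 uM


def calibrate_system(rates: dict[str, float],
                     receptor_count: float | None = None,
                     capture_ratios: dict[str, float] | None = None,
                     base_config: dict | None = None,
                     tolerance: float = 0.1) -> CalibrationOutcome:
    """Build a system whose rates match measured release and capture data.

    Parameters
    ----------
    rates : dict
        Ligand name -> measured k_Q*P in molecules/cell/min.  Every ligand
        that appears anywhere (rates or capture_ratios) must have a rate.
    receptor_count : float, optional
        Measured receptors/cell; overrides the default R0.
    capture_ratios : dict, optional
        Ligand name -> measured bulk-free-ligand fraction.  For each, the
        ligand's K_D is tuned by bounded search on log10 K_D (all other
        constants frozen) so the simulated paired +/- blockade fraction
        reproduces the measurement.
    tolerance : float
        Maximum acceptable |achieved - target|; larger residuals are
        reported in ``failures`` (never silently accepted).
    """
    capture_ratios = capture_ratios or {}
    if not rates:
        raise ConfigError("at least one ligand release rate is required")
    missing = sorted(set(capture_ratios) - set(rates))
    if missing:
        raise ConfigError("capture ratio supplied without a release rate "
                          f"for ligand(s): {missing}")
    for name, target in capture_ratios.items():
        if not 0.0 <= target <= 1.0:
            raise ConfigError(f"capture ratio for {name!r} must be in [0, 1]")

    cfg = base_config if base_config is not None else default_config()
    known = {l["name"]: dict(l) for l in cfg["ligands"]}
    lig_cfgs = []
    for name, rate in rates.items():
        if rate < 0:
            raise ConfigError(f"release rate for {name!r} must be >= 0")
        lig = known.get(name, {"name": name, "kd_nM": 1.0})
        lig["release_rate"] = float(rate)
        lig_cfgs.append(lig)
    cfg = {**cfg, "ligands": lig_cfgs}
    if receptor_count is not None:
        cfg["receptor"] = {**cfg.get("receptor", {}), "r0": float(receptor_count)}

    outcome = CalibrationOutcome(system=build_system(cfg))

    for name, target in capture_ratios.items():
        if outcome.system.receptor.r0 <= 0 and target < 1.0:
            raise ConfigError(
                f"capture ratio {target} for {name!r} is infeasible with "
                "zero receptors (no capture is possible)")
        single = build_system({**cfg, "ligands": [
            l for l in lig_cfgs if l["name"] == name]})

        def objective(log_kd: float) -> float:
            sys_i = single.with_ligand(name, kd_nM=10.0 ** log_kd)
            return (free_ligand_fraction(sys_i, name) - target) ** 2

        res = minimize_scalar(objective, bounds=_LOG_KD_BOUNDS,
                              method="bounded",
                              options={"xatol": 1e-3})
        log_kd = float(res.x)
        kd = 10.0 ** log_kd
        achieved = free_ligand_fraction(single.with_ligand(name, kd_nM=kd),
                                        name)
        outcome.fitted_kd_nM[name] = kd
        outcome.achieved_free_fraction[name] = achieved
        at_edge = (log_kd - _LOG_KD_BOUNDS[0] < 0.05
                   or _LOG_KD_BOUNDS[1] - log_kd < 0.05)
        if at_edge:
            outcome.boundary_flags[name] = (
                "fitted K_D at search-range boundary "
                f"({10.0 ** _LOG_KD_BOUNDS[0]:g}-"
                f"{10.0 ** _LOG_KD_BOUNDS[1]:g} nM)")
        if abs(achieved - target) > tolerance:
            outcome.failures[name] = (
                f"calibrated free fraction {achieved:.3f} misses target "
                f"{target:.3f} by more than {tolerance}")
        outcome.system = outcome.system.with_ligand(name, kd_nM=kd)
    return outcome
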