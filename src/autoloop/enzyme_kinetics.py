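"""Inhibitor potency from recombinant-enzyme FRET assays.

A purified sheddase (e.g. recombinant ADAM12 at 5 nM) is pre-incubated
with an inhibitor dilution series (6-point, 3-fold serial by default) and
mixed with a FRET-quenched peptide substrate; the initial rate of
fluorescence increase measures residual activity.  The dose-response is
fit with the one-site hyperbola

    v(I) = v0 * (1 - I / (I + IC50)),

and, when the IC50 approaches the enzyme concentration (so free and total
inhibitor diverge), with the Morrison tight-binding quadratic

    v(I) = v0 * (1 - (E + I + K - sqrt((E + I + K)^2 - 4 E I)) / (2 E)).

K_i follows from the fitted constant by the classical competitive
correction K_i = IC50 / (1 + S/K_M) when the substrate K_M is known;
otherwise K_i is reported as the uncorrected fit constant with a flag
(at S far below K_M the two coincide).  Confidence intervals come from a
seeded residual bootstrap.  Flat curves (< 10% inhibition at the top
dose) are reported as "no detectable inhibition" with a lower bound on
K_i rather than as a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "InhibitionAssay",
    "RateEstimate",
    "InhibitionFit",
    "initial_rate",
    "fit_inhibition",
    "specificity_panel",
    "NO_INHIBITION_THRESHOLD",
]

#: maximum fractional rate reduction at the top dose still called flat
NO_INHIBITION_THRESHOLD = 0.10

#: IC50/E ratio below which the Morrison model replaces the hyperbola
TIGHT_BINDING_RATIO = 10.0


class FitQualityError(RuntimeError):
    """Dose-response data incompatible with a monotone inhibition curve."""


@dataclass(frozen=True)
class RateEstimate:
    """Initial velocity with linearity diagnostics."""

    slope: float
    stderr: float
    curvature_t: float  # t-statistic of the quadratic term; |t|>~3 = curved
    window: tuple[float, float] = (0.0, float("inf"))


def initial_rate(times_min, fluorescence, window_min: float | None = None
                 ) -> RateEstimate:
    """OLS slope of a fluorescence time course over an early-linear window.

    ``window_min`` restricts the fit to t <= window_min (substrate
    depletion bends later points).  The attached curvature t-statistic
    (from a quadratic refit over the same window) flags nonlinearity.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if window_min is not None:
        keep = t <= window_min
        t, y = t[keep], y[keep]
    if len(t) < 3:
        raise ValueError("need >= 3 finite timepoints in the fit window")
    x = np.column_stack([np.ones_like(t), t])
    beta, res, *_ = np.linalg.lstsq(x, y, rcond=None)
    dof = len(t) - 2
    sigma2 = float(res[0]) / dof if len(res) and dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(x.T @ x)
    slope, stderr = float(beta[1]), float(np.sqrt(max(cov[1, 1], 0.0)))
    curvature_t = 0.0
    if len(t) >= 4:
        xq = np.column_stack([np.ones_like(t), t, t ** 2])
        bq, rq, *_ = np.linalg.lstsq(xq, y, rcond=None)
        dofq = len(t) - 3
        s2 = float(rq[0]) / dofq if len(rq) and dofq > 0 else 0.0
        covq = s2 * np.linalg.inv(xq.T @ xq)
        se = float(np.sqrt(max(covq[2, 2], 0.0)))
        # numerically exact data: the quadratic term is float dust, not
        # curvature
        scale = float(np.max(np.abs(y))) or 1.0
        if se > 0 and abs(bq[2]) * np.ptp(t) ** 2 > 1e-9 * scale:
            curvature_t = float(bq[2] / se)
    return RateEstimate(slope=slope, stderr=stderr, curvature_t=curvature_t,
                        window=(float(t[0]), float(t[-1])))


@dataclass
class InhibitionAssay:
    """An inhibitor dilution series against one recombinant enzyme.

    ``rates`` maps each dose to one or more replicate initial velocities
    (shape (n_doses, n_replicates), NaN-padded if ragged).  The dose grid
    must include 0 (or the caller supplies ``v0_reference``) so the
    uninhibited rate is anchored.
    """

    enzyme: str
    doses_nM: np.ndarray
    rates: np.ndarray
    enzyme_conc_nM: float = 5.0
    substrate_conc_uM: float = 15.0
    preincubation_min: float = 10.0
    v0_reference: float | None = None

    def __post_init__(self) -> None:
        self.doses_nM = np.asarray(self.doses_nM, dtype=float)
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if self.rates.shape[0] != len(self.doses_nM):
            raise ValueError("rates must have one row per dose")
        if np.any(self.doses_nM < 0):
            raise ValueError("doses must be >= 0")
        if np.nanmin(self.rates) < 0:
            raise ValueError("rates must be >= 0")
        if 0.0 not in self.doses_nM and self.v0_reference is None:
            raise ValueError("dose grid must include 0 or an explicit "
                             "uninhibited v0_reference")
        if self.enzyme_conc_nM <= 0:
            raise ValueError("enzyme_conc_nM must be > 0")

    @property
    def mean_rates(self) -> np.ndarray:
        return np.nanmean(self.rates, axis=1)


@dataclass
class InhibitionFit:
    """Fitted inhibitor potency for one enzyme.

    When ``no_inhibition`` is set, ``ki_nM``/``ic50_nM`` are NaN and
    ``ki_lower_bound_nM`` states the detection limit (top dose tested).
    ``km_corrected`` records whether the classical substrate-competition
    correction was applied to derive K_i.
    """

    enzyme: str
    ic50_nM: float
    ki_nM: float
    model: str  # "hyperbolic" | "tight-binding" | "none"
    v0: float
    no_inhibition: bool = False
    ki_lower_bound_nM: float | None = None
    km_corrected: bool = False
    ic50_ci_nM: tuple[float, float] | None = None
    ki_ci_nM: tuple[float, float] | None = None
    diagnostics: dict = field(default_factory=dict)


def _hyperbolic(dose, v0, ic50):
    return v0 * (1.0 - dose / (dose + ic50))


def _morrison(dose, v0, kapp, e_tot):
    s = e_tot + dose + kapp
    frac = (s - np.sqrt(s * s - 4.0 * e_tot * dose)) / (2.0 * e_tot)
    return v0 * (1.0 - frac)


def _fit_model(doses, rates, v0_guess, e_tot, model) -> lmfit.model.ModelResult:
    if model == "hyperbolic":
        m = lmfit.Model(_hyperbolic)
    else:
        m = lmfit.Model(_morrison, independent_vars=["dose"])
    params = m.make_params()
    params["v0"].set(value=v0_guess, min=0)
    key = "ic50" if model == "hyperbolic" else "kapp"
    top = max(doses.max(), e_tot) * 10
    params[key].set(value=max(np.median(doses[doses > 0]), 1e-3),
                    min=1e-9, max=top * 100)
    kwargs = {"dose": doses}
    if model != "hyperbolic":
        params["e_tot"] = lmfit.Parameter("e_tot", value=e_tot, vary=False)
    return m.fit(rates, params, **kwargs)


def _check_monotone(doses, means, v0, noise_sd):
    """Reject curves that rise with dose beyond what noise explains."""
    tol = 4.0 * noise_sd + 0.15 * v0
    order = np.argsort(doses)
    m = means[order]
    running_min = np.minimum.accumulate(m)
    if np.any(m - running_min > tol):
        raise FitQualityError(
            "rates increase with dose beyond noise tolerance; "
            "not a monotone inhibition curve")


def fit_inhibition(assay: InhibitionAssay, km_uM: float | None = None,
                   n_boot: int = 200, seed: int = 0) -> InhibitionFit:
    """Fit a dilution series and report IC50 and K_i.

    Model selection: hyperbolic first; if the fitted IC50 is within
    ``TIGHT_BINDING_RATIO`` times the enzyme concentration, enzyme
    depletion matters and the Morrison quadratic is refit and reported.
    Set ``n_boot=0`` to skip bootstrap confidence intervals.
    """
    doses = assay.doses_nM
    finite = np.isfinite(assay.mean_rates)
    if (doses[finite] > 0).sum() + (0.0 in doses) < 4:
        raise ValueError("need >= 4 distinct doses with finite rates")
    means = assay.mean_rates
    if assay.v0_reference is not None:
        v0_obs = float(assay.v0_reference)
    else:
        v0_obs = float(means[doses == 0.0].mean())
    if v0_obs <= 0:
        raise ValueError("uninhibited rate must be > 0")

    top = float(doses.max())
    top_rate = float(means[doses == top].mean())
    observed_inhibition = 1.0 - top_rate / v0_obs

    def _flat_result(max_inhibition):
        return InhibitionFit(
            enzyme=assay.enzyme, ic50_nM=float("nan"), ki_nM=float("nan"),
            model="none", v0=v0_obs, no_inhibition=True,
            ki_lower_bound_nM=top,
            diagnostics={"max_inhibition": max_inhibition})

    if observed_inhibition < NO_INHIBITION_THRESHOLD:
        # flat within the detection criterion: report a bound, never a fit
        return _flat_result(observed_inhibition)

    if assay.rates.shape[1] > 1:
        rep_sd = np.nanstd(assay.rates, axis=1, ddof=1)
        noise_sd = float(np.nanmean(rep_sd[np.isfinite(rep_sd)])) \
            if np.isfinite(rep_sd).any() else 0.0
    else:
        noise_sd = 0.0
    _check_monotone(doses, means, v0_obs, noise_sd)

    # flatten replicates for the fit
    d_flat = np.repeat(doses, assay.rates.shape[1])
    r_flat = assay.rates.ravel()
    ok = np.isfinite(r_flat)
    d_flat, r_flat = d_flat[ok], r_flat[ok]

    fit = _fit_model(d_flat, r_flat, v0_obs, assay.enzyme_conc_nM,
                     "hyperbolic")
    # the fitted curve pools all doses, so its predicted reduction at the
    # top dose is a far less noisy flatness statistic than the single
    # top-dose pair of replicates
    fitted_inhibition = top / (top + float(fit.params["ic50"].value))
    if fitted_inhibition < NO_INHIBITION_THRESHOLD:
        return _flat_result(fitted_inhibition)
    model = "hyperbolic"
    const = float(fit.params["ic50"].value)
    if const <= TIGHT_BINDING_RATIO * assay.enzyme_conc_nM:
        fit = _fit_model(d_flat, r_flat, v0_obs, assay.enzyme_conc_nM,
                         "tight-binding")
        model = "tight-binding"
        const = float(fit.params["kapp"].value)
        # apparent IC50 of a tight binder includes half the enzyme
        ic50 = const + assay.enzyme_conc_nM / 2.0
    else:
        ic50 = const
    if km_uM is not None:
        ki = const / (1.0 + assay.substrate_conc_uM / km_uM)
        km_corrected = True
    else:
        ki = const
        km_corrected = False

    ic50_ci = ki_ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        resid = r_flat - fit.best_fit
        consts = []
        for _ in range(n_boot):
            sample = fit.best_fit + rng.choice(resid, size=len(resid),
                                               replace=True)
            sample = np.clip(sample, 0.0, None)
            try:
                bfit = _fit_model(d_flat, sample, v0_obs,
                                  assay.enzyme_conc_nM, model)
            except Exception:
                continue
            key = "ic50" if model == "hyperbolic" else "kapp"
            consts.append(float(bfit.params[key].value))
        if len(consts) >= max(20, n_boot // 4):
            lo, hi = np.percentile(consts, [2.5, 97.5])
            shift = assay.enzyme_conc_nM / 2.0 if model == "tight-binding" \
                else 0.0
            ic50_ci = (float(lo) + shift, float(hi) + shift)
            corr = (1.0 + assay.substrate_conc_uM / km_uM) if km_corrected \
                else 1.0
            ki_ci = (float(lo) / corr, float(hi) / corr)

    return InhibitionFit(
        enzyme=assay.enzyme, ic50_nM=float(ic50), ki_nM=float(ki),
        model=model, v0=float(fit.params["v0"].value),
        km_corrected=km_corrected, ic50_ci_nM=ic50_ci, ki_ci_nM=ki_ci,
        diagnostics={"redchi": float(fit.redchi),
                     "max_inhibition": observed_inhibition})


def specificity_panel(fits: dict[str, InhibitionFit] | list[InhibitionFit]
                      ) -> pd.DataFrame:
    """Cross-enzyme potency table with fold-selectivity of the best hit.

    Enzymes flagged no-inhibition enter as lower bounds (``K_i >= top
    dose``); the selectivity of the most potently inhibited enzyme over
    the runner-up is then itself a bound and is prefixed ``>=``.
    """
    if not isinstance(fits, dict):
        fits = {f.enzyme: f for f in fits}
    if len(fits) < 2:
        raise ValueError("a specificity panel needs >= 2 enzymes")
    rows = []
    for enzyme, f in fits.items():
        rows.append({
            "enzyme": enzyme,
            "ki_nM": f.ki_nM,
            "ki_display": (f"> {f.ki_lower_bound_nM:g}" if f.no_inhibition
                           else f"{f.ki_nM:g}"),
            "model": f.model,
            "no_inhibition": f.no_inhibition,
        })
    table = pd.DataFrame(rows).set_index("enzyme")
    inhibited = table[~table["no_inhibition"]].sort_values("ki_nM")
    table["selectivity"] = ""
    if len(inhibited) == 0:
        return table  # no selectivity claim possible
    best = inhibited.index[0]
    others = table.drop(index=best)
    ref_vals = [(r["ki_nM"] if not r["no_inhibition"]
                 else fits[e].ki_lower_bound_nM, r["no_inhibition"])
                for e, r in others.iterrows()]
    runner_up, is_bound = min(ref_vals, key=lambda t: t[0])
    fold = runner_up / table.loc[best, "ki_nM"]
    table.loc[best, "selectivity"] = (f">= {fold:.3g}-fold" if is_bound
                                      else f"{fold:.3g}-fold")
    return table
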