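"""Cue-signal-response analysis: from FRET cleavage panels to sheddase
attribution.

The pipeline mirrors a live-cell protease profiling experiment.  Cells are
stimulated with a panel of growth-factor/cytokine "cues" (with and without
a receptor-blocking antibody); a cocktail of FRET-quenched polypeptide
substrates reports cleavage as a linear fluorescence increase; specific
ADAM activities ("signals") are deconvolved from the per-substrate
cleavage rates through a protease x substrate catalytic-efficiency
signature matrix by non-negative least squares (the inferential core of
protease activity matrix analysis, here as a reduced faithful variant with
optional substrate-subset ensembling rather than the full published
ensemble machinery); and 24-h supernatant accumulation of endogenous
ADAM substrates ("responses") is normalized per cell after subtracting a
broad-spectrum-inhibitor background.  Pearson correlation of activities
against responses across conditions then ranks candidate sheddases per
substrate.

Tables are pandas DataFrames throughout: cleavage rates and activities are
conditions x (substrates|proteases); correlation matrices are proteases x
substrates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

__all__ = [
    "FretPanel",
    "SignatureMatrix",
    "CleavageRates",
    "ActivityTable",
    "ResponseTable",
    "CorrelationResult",
    "cleavage_rates",
    "infer_activities",
    "normalize_responses",
    "correlate",
    "rank_sheddases",
]

log = logging.getLogger(__name__)


class PipelineError(ValueError):
    """Invalid or degenerate pipeline input."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FretPanel:
    """Fluorescence time courses: (condition, substrate, replicate, time).

    ``fluorescence`` has shape (n_conditions, n_substrates, n_replicates,
    n_timepoints) in arbitrary units; missing wells are NaN.
    """

    conditions: list[str]
    substrates: list[str]
    timepoints_min: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        t = self.timepoints_min
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise PipelineError("need >= 2 strictly increasing timepoints")
        expected = (len(self.conditions), len(self.substrates))
        if self.fluorescence.ndim != 4 or \
                self.fluorescence.shape[:2] != expected or \
                self.fluorescence.shape[3] != len(t):
            raise PipelineError(
                f"fluorescence shape {self.fluorescence.shape} does not "
                f"match (conditions, substrates, replicates, timepoints)")
        dead = np.all(np.isnan(self.fluorescence), axis=(0, 2, 3))
        if np.any(dead):
            bad = [s for s, d in zip(self.substrates, dead) if d]
            raise PipelineError(f"substrate series wholly missing: {bad}")

    def to_frame(self) -> pd.DataFrame:
        """Long format (condition, substrate, replicate, time_min,
        fluorescence)."""
        n_c, n_s, n_r, n_t = self.fluorescence.shape
        idx = pd.MultiIndex.from_product(
            [self.conditions, self.substrates, range(n_r),
             self.timepoints_min],
            names=["condition", "substrate", "replicate", "time_min"])
        return (pd.DataFrame({"fluorescence": self.fluorescence.ravel()},
                             index=idx).reset_index())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FretPanel":
        required = {"condition", "substrate", "replicate", "time_min",
                    "fluorescence"}
        missing = required - set(df.columns)
        if missing:
            raise PipelineError(f"FRET table missing columns {sorted(missing)}")
        conditions = list(pd.unique(df["condition"]))
        substrates = list(pd.unique(df["substrate"]))
        reps = sorted(pd.unique(df["replicate"]))
        times = np.sort(pd.unique(df["time_min"]).astype(float))
        arr = np.full((len(conditions), len(substrates), len(reps),
                       len(times)), np.nan)
        pos_c = {c: i for i, c in enumerate(conditions)}
        pos_s = {s: i for i, s in enumerate(substrates)}
        pos_r = {r: i for i, r in enumerate(reps)}
        pos_t = {t: i for i, t in enumerate(times)}
        for row in df.itertuples(index=False):
            arr[pos_c[row.condition], pos_s[row.substrate],
                pos_r[row.replicate], pos_t[float(row.time_min)]] = \
                row.fluorescence
        return cls(conditions, substrates, times, arr)


@dataclass
class SignatureMatrix:
    """Substrates x proteases catalytic-efficiency signature.

    Entries are specificity constants (per concentration per time, any
    consistent unit); a protease whose column is all zero would be
    unidentifiable and is rejected.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table.values < 0).any():
            raise PipelineError("signature entries must be >= 0")
        zero_cols = self.table.columns[(self.table == 0).all(axis=0)]
        if len(zero_cols):
            raise PipelineError(
                f"all-zero signature column(s) {list(zero_cols)}: protease "
                "indistinguishable from absent")

    @property
    def substrates(self) -> list[str]:
        return list(self.table.index)

    @property
    def proteases(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class CleavageRates:
    """Replicate-mean OLS cleavage rates (conditions x substrates) + SEM."""

    mean: pd.DataFrame
    sem: pd.DataFrame
    n_replicates: pd.DataFrame


@dataclass
class ActivityTable:
    """Inferred protease activities (conditions x proteases), >= 0."""

    activities: pd.DataFrame
    dispersion: pd.DataFrame | None = None
    residual: pd.Series | None = None


@dataclass
class ResponseTable:
    """Normalized per-cell shedding responses (conditions x analytes)."""

    responses: pd.DataFrame
    clamped: pd.DataFrame = None


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations of activities vs responses.

    ``r``, ``p`` and ``n`` are proteases x substrates DataFrames; pairs
    with undefined correlation (zero variance, n < 3) are NaN in ``r``
    and ``p``.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tm, ym = t.mean(), y.mean()
    return float(((t - tm) * (y - ym)).sum() / ((t - tm) ** 2).sum())


def cleavage_rates(panel: FretPanel) -> CleavageRates:
    """Per-condition/substrate cleavage rate from the fluorescence slope.

    Each replicate contributes the ordinary-least-squares slope of its
    fluorescence time course; replicates with fewer than two finite
    timepoints are dropped with a warning, and a cell whose replicates are
    all dropped is an error.
    """
    n_c, n_s, n_r, _ = panel.fluorescence.shape
    mean = np.empty((n_c, n_s))
    sem = np.empty((n_c, n_s))
    nrep = np.empty((n_c, n_s), dtype=int)
    t = panel.timepoints_min
    for i in range(n_c):
        for j in range(n_s):
            slopes = []
            for k in range(n_r):
                y = panel.fluorescence[i, j, k]
                ok = np.isfinite(y)
                if ok.sum() < 2:
                    log.warning(
                        "dropping replicate %d of (%s, %s): <2 finite "
                        "timepoints", k, panel.conditions[i],
                        panel.substrates[j])
                    continue
                slopes.append(_ols_slope(t[ok], y[ok]))
            if not slopes:
                raise PipelineError(
                    f"no usable replicate for condition "
                    f"{panel.conditions[i]!r}, substrate "
                    f"{panel.substrates[j]!r}")
            slopes = np.array(slopes)
            mean[i, j] = slopes.mean()
            sem[i, j] = (slopes.std(ddof=1) / np.sqrt(len(slopes))
                         if len(slopes) > 1 else np.nan)
            nrep[i, j] = len(slopes)
    kw = dict(index=panel.conditions, columns=panel.substrates)
    return CleavageRates(mean=pd.DataFrame(mean, **kw),
                         sem=pd.DataFrame(sem, **kw),
                         n_replicates=pd.DataFrame(nrep, **kw))


def _nnls_solve(sig: np.ndarray, rates: np.ndarray) -> tuple[np.ndarray, float]:
    x, rnorm = nnls(sig, rates)
    return x, rnorm


def infer_activities(rates: CleavageRates | pd.DataFrame,
                     signature: SignatureMatrix,
                     ensemble_size: int | None = None) -> ActivityTable:
    """Deconvolve protease activities from substrate cleavage rates.

    Per condition, solves ``rates ~ signature @ activities`` with
    non-negative least squares.  With ``ensemble_size = k`` (default: one
    less than the number of substrates; pass 0 to disable ensembling), the
    solution is averaged over every substrate subset of size k whose
    signature sub-matrix has full column rank, and the across-subset
    standard deviation is reported as dispersion.
    """
    rates_df = rates.mean if isinstance(rates, CleavageRates) else rates
    missing = set(signature.substrates) - set(rates_df.columns)
    if missing:
        raise PipelineError(f"rate table lacks substrate(s) {sorted(missing)}")
    rates_df = rates_df[signature.substrates]
    sig = signature.table.values
    n_sub, n_prot = sig.shape
    if n_sub < n_prot:
        raise PipelineError(
            f"{n_sub} substrates cannot identify {n_prot} proteases")
    if ensemble_size is None:
        ensemble_size = n_sub - 1 if n_sub > n_prot else 0
    if ensemble_size and not (n_prot <= ensemble_size <= n_sub):
        raise PipelineError("ensemble subset size must lie between the "
                            "number of proteases and of substrates")

    act = np.empty((len(rates_df), n_prot))
    disp = np.full((len(rates_df), n_prot), np.nan)
    resid = np.empty(len(rates_df))
    for i, (_, row) in enumerate(rates_df.iterrows()):
        # negative measured rates are noise around zero; NNLS input stays raw
        b = row.values.astype(float)
        if ensemble_size in (0, n_sub):
            act[i], resid[i] = _nnls_solve(sig, b)
            continue
        solutions = []
        for subset in itertools.combinations(range(n_sub), ensemble_size):
            sub = sig[list(subset)]
            if np.linalg.matrix_rank(sub) < n_prot:
                log.info("skipping rank-deficient substrate subset %s",
                         subset)
                continue
            x, _ = _nnls_solve(sub, b[list(subset)])
            solutions.append(x)
        if not solutions:
            raise PipelineError(
                "every substrate subset was rank-deficient; cannot "
                "ensemble-infer activities")
        solutions = np.array(solutions)
        act[i] = solutions.mean(axis=0)
        disp[i] = solutions.std(axis=0, ddof=1) if len(solutions) > 1 else 0.0
        resid[i] = float(np.linalg.norm(sig @ act[i] - b))
    kw = dict(index=rates_df.index, columns=signature.proteases)
    return ActivityTable(activities=pd.DataFrame(act, **kw),
                         dispersion=pd.DataFrame(disp, **kw),
                         residual=pd.Series(resid, index=rates_df.index))


def normalize_responses(raw: pd.DataFrame, cell_counts: pd.Series,
                        backgrounds: pd.DataFrame,
                        volume_ml: float = 0.1) -> ResponseTable:
    """Background-correct and per-cell normalize supernatant accumulation.

    ``entry = max(0, raw - background) * volume / cells`` — raw and
    background in concentration units (e.g. pg/mL), giving amount per
    cell.  Negative corrected values clamp to zero with a flag.
    """
    missing_bg = set(raw.index) - set(backgrounds.index)
    if missing_bg:
        raise PipelineError(
            f"condition(s) without background control: {sorted(missing_bg)}")
    missing_cells = set(raw.index) - set(cell_counts.index)
    if missing_cells:
        raise PipelineError(
            f"condition(s) without cell count: {sorted(missing_cells)}")
    bg = backgrounds.reindex(index=raw.index, columns=raw.columns)
    if bg.isna().any().any():
        bad = [c for c in raw.columns if bg[c].isna().any()]
        raise PipelineError(f"background missing for analyte(s) {bad}")
    net = raw - bg
    clamped = net < 0
    net = net.clip(lower=0.0)
    per_cell = net.mul(volume_ml).div(cell_counts.reindex(raw.index), axis=0)
    return ResponseTable(responses=per_cell, clamped=clamped)


def correlate(activities: ActivityTable | pd.DataFrame,
              responses: ResponseTable | pd.DataFrame,
              condition_subset=None) -> CorrelationResult:
    """Pearson-correlate each protease activity against each shedding
    response across conditions.

    ``condition_subset`` selects the conditions entering the correlation
    (e.g. only the receptor-blockaded arm for EGF-family ligands, where
    uptake would otherwise confound accumulation).  Pairs are excluded
    pairwise for missing values; two-tailed p-values come from the exact
    t-transform ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.
    """
    act = (activities.activities if isinstance(activities, ActivityTable)
           else activities)
    resp = (responses.responses if isinstance(responses, ResponseTable)
            else responses)
    if condition_subset is not None:
        condition_subset = list(condition_subset)
        act = act.loc[[c for c in condition_subset if c in act.index]]
        resp = resp.loc[[c for c in condition_subset if c in resp.index]]
    shared = [c for c in act.index if c in set(resp.index)]
    if len(shared) < 3:
        raise PipelineError(
            f"need >= 3 shared conditions, got {len(shared)}")
    act = act.loc[shared]
    resp = resp.loc[shared]
    prot, subs = list(act.columns), list(resp.columns)
    r = pd.DataFrame(np.nan, index=prot, columns=subs)
    p = pd.DataFrame(np.nan, index=prot, columns=subs)
    n = pd.DataFrame(0, index=prot, columns=subs)
    for pr in prot:
        for su in subs:
            x = act[pr].values.astype(float)
            y = resp[su].values.astype(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n.loc[pr, su] = int(ok.sum())
            if ok.sum() < 3:
                continue
            x, y = x[ok], y[ok]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # undefined, reported as missing
            res = stats.pearsonr(x, y)
            r.loc[pr, su] = res.statistic
            p.loc[pr, su] = res.pvalue
    return CorrelationResult(r=r, p=p, n=n)


def rank_sheddases(corr: CorrelationResult, substrate: str) -> list[str]:
    """Proteases ranked as candidate sheddases of one substrate.

    Sorted by descending Pearson r; ties broken by ascending p, then by
    protease label for determinism.  Proteases with undefined r are
    omitted; a wholly undefined column is an error.
    """
    if substrate not in corr.r.columns:
        raise PipelineError(f"no substrate {substrate!r} in correlation "
                            f"result; have {list(corr.r.columns)}")
    col_r = corr.r[substrate]
    defined = col_r.dropna().index
    if len(defined) == 0:
        raise PipelineError(
            f"all correlations undefined for substrate {substrate!r}")
    entries = [(-col_r[pr], corr.p[substrate][pr], pr) for pr in defined]
    return [pr for _, _, pr in sorted(entries)]
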