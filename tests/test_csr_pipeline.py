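"""Cue-signal-response pipeline: slopes, NNLS deconvolution, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from autoloop import csr_pipeline as csr
from autoloop import synthetic_data as sd


def _panel(fluor, times=(0.0, 1.0, 2.0, 3.0, 4.0)):
    fluor = np.asarray(fluor, dtype=float)
    n_c, n_s = fluor.shape[:2]
    return csr.FretPanel(conditions=[f"c{i}" for i in range(n_c)],
                         substrates=[f"s{j}" for j in range(n_s)],
                         timepoints_min=np.asarray(times),
                         fluorescence=fluor)


class TestCleavageRates:
    def test_constant_series_zero_slope(self):
        panel = _panel(np.full((1, 1, 2, 5), 7.0))
        assert csr.cleavage_rates(panel).mean.iloc[0, 0] == 0.0

    def test_exact_line(self):
        y = np.arange(5.0)[None, None, None, :].repeat(3, axis=2)
        panel = _panel(y)
        assert csr.cleavage_rates(panel).mean.iloc[0, 0] == pytest.approx(1.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(7)
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 3.0 + 0.8 * t + rng.normal(0, 0.3, 5)
        panel = _panel(y[None, None, None, :])
        # independent closed-form OLS slope on the same numbers
        expected = (np.sum((t - t.mean()) * (y - y.mean()))
                    / np.sum((t - t.mean()) ** 2))
        assert csr.cleavage_rates(panel).mean.iloc[0, 0] == \
            pytest.approx(expected, rel=1e-12)

    def test_short_replicate_dropped_then_error_when_all_gone(self):
        y = np.arange(5.0)[None, None, None, :].repeat(2, axis=2).copy()
        y[0, 0, 1, 2:] = np.nan  # replicate 1 keeps only 2 points: kept
        panel = _panel(y)
        rates = csr.cleavage_rates(panel)
        assert rates.n_replicates.iloc[0, 0] == 2
        y[0, 0, :, 1:] = np.nan  # all replicates below 2 finite points
        with pytest.raises(csr.PipelineError, match="no usable replicate"):
            csr.cleavage_rates(_panel(y))

    def test_long_frame_round_trip(self):
        act = sd.gen_activities(3, conditions=["a", "b", "c"])
        panel, _ = sd.gen_fret_panel(act, seed=3)
        back = csr.FretPanel.from_frame(panel.to_frame())
        assert np.allclose(back.fluorescence, panel.fluorescence,
                           equal_nan=True)


def _grid_oracle(sig, b, upper, step=1e-3):
    """Exhaustive non-negative grid search for min ||sig @ x - b||."""
    axes = [np.arange(0.0, upper + step / 2, step)] * sig.shape[1]
    best, best_x = np.inf, None
    # vectorize over the first axis to keep memory flat
    grid1 = axes[0]
    for x1 in axes[1] if sig.shape[1] == 2 else [None]:
        if x1 is None:
            resid = sig[:, :1] * grid1[None, :] - b[:, None]
            norms = np.linalg.norm(resid, axis=0)
            k = int(np.argmin(norms))
            if norms[k] < best:
                best, best_x = norms[k], np.array([grid1[k]])
        else:
            pred = sig[:, :1] * grid1[None, :] + sig[:, 1:2] * x1
            norms = np.linalg.norm(pred - b[:, None], axis=0)
            k = int(np.argmin(norms))
            if norms[k] < best:
                best, best_x = norms[k], np.array([grid1[k], x1])
    return best_x


class TestInferActivities:
    def test_identity_signature(self):
        sig = csr.SignatureMatrix(pd.DataFrame(
            np.eye(4), index=list("wxyz"), columns=list("ABCD")))
        rates = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["c"],
                             columns=list("wxyz"))
        table = csr.infer_activities(rates, sig, ensemble_size=0)
        assert np.allclose(table.activities.values, [[1, 2, 3, 4]])

    def test_exact_recovery_on_consistent_system(self):
        rng = np.random.default_rng(11)
        sig = sd.default_signature()
        a_true = rng.uniform(0.1, 3.0, (5, 4))
        rates = pd.DataFrame(a_true @ sig.table.values.T,
                             index=[f"c{i}" for i in range(5)],
                             columns=sig.substrates)
        table = csr.infer_activities(rates, sig, ensemble_size=0)
        assert np.allclose(table.activities.values, a_true, rtol=1e-6)

    def test_nonnegativity_binds_matches_grid_oracle(self):
        # a latent negative component must clamp to zero with residual > 0
        sig_arr = np.array([[1.0, 0.3], [0.2, 1.0]])
        b = sig_arr @ np.array([1.5, -0.5])
        sig = csr.SignatureMatrix(pd.DataFrame(
            sig_arr, index=["s1", "s2"], columns=["P1", "P2"]))
        rates = pd.DataFrame([b], index=["c"], columns=["s1", "s2"])
        table = csr.infer_activities(rates, sig, ensemble_size=0)
        x = table.activities.values[0]
        assert x[1] == 0.0
        assert table.residual.iloc[0] > 0.0
        oracle = _grid_oracle(sig_arr, b, upper=2.0)
        assert np.allclose(x, oracle, atol=2e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_sub = rng.integers(2, 4)
        sig_arr = rng.uniform(0.1, 1.0, (n_sub, 2))
        b = rng.uniform(-0.2, 1.0, n_sub)
        sig = csr.SignatureMatrix(pd.DataFrame(
            sig_arr, index=[f"s{i}" for i in range(n_sub)],
            columns=["P1", "P2"]))
        rates = pd.DataFrame([b], index=["c"],
                             columns=[f"s{i}" for i in range(n_sub)])
        x = csr.infer_activities(rates, sig,
                                 ensemble_size=0).activities.values[0]
        oracle = _grid_oracle(sig_arr, b, upper=3.0)
        assert np.allclose(x, oracle, atol=5e-3)

    def test_underdetermined_rejected(self):
        sig = csr.SignatureMatrix(pd.DataFrame(
            np.ones((2, 3)), index=["s1", "s2"], columns=["a", "b", "c"]))
        rates = pd.DataFrame([[1.0, 1.0]], index=["c"],
                             columns=["s1", "s2"])
        with pytest.raises(csr.PipelineError, match="identify"):
            csr.infer_activities(rates, sig)

    def test_all_zero_signature_column_rejected(self):
        with pytest.raises(csr.PipelineError, match="all-zero"):
            csr.SignatureMatrix(pd.DataFrame(
                [[1.0, 0.0], [1.0, 0.0]], index=["s1", "s2"],
                columns=["a", "b"]))

    def test_ensemble_dispersion_reported(self):
        act = sd.gen_activities(5, conditions=["a", "b", "c", "d"])
        panel, _ = sd.gen_fret_panel(act, seed=5, noise_scale=0.05)
        table = csr.infer_activities(csr.cleavage_rates(panel),
                                     sd.default_signature())
        assert table.dispersion.shape == table.activities.shape
        assert (table.activities.values >= 0).all()


class TestNormalizeResponses:
    RAW = pd.DataFrame({"HB-EGF": [10.0, 3.0]}, index=["a", "b"])
    BG = pd.DataFrame({"HB-EGF": [4.0, 4.0]}, index=["a", "b"])
    CELLS = pd.Series([1e5, 1e5], index=["a", "b"])

    def test_arithmetic(self):
        table = csr.normalize_responses(self.RAW, self.CELLS, self.BG,
                                        volume_ml=0.1)
        assert table.responses.loc["a", "HB-EGF"] == pytest.approx(6e-6)

    def test_raw_below_background_clamps_with_flag(self):
        table = csr.normalize_responses(self.RAW, self.CELLS, self.BG,
                                        volume_ml=0.1)
        assert table.responses.loc["b", "HB-EGF"] == 0.0
        assert table.clamped.loc["b", "HB-EGF"]

    def test_raw_equal_background_all_zero(self):
        table = csr.normalize_responses(self.BG, self.CELLS, self.BG)
        assert (table.responses.values == 0.0).all()

    def test_missing_background_names_condition(self):
        with pytest.raises(csr.PipelineError, match="background"):
            csr.normalize_responses(self.RAW, self.CELLS, self.BG.iloc[:1])

    def test_missing_cell_count_names_condition(self):
        with pytest.raises(csr.PipelineError, match="cell count"):
            csr.normalize_responses(self.RAW, self.CELLS.iloc[:1], self.BG)


class TestCorrelate:
    def _tables(self, act, resp):
        a = pd.DataFrame({"P": act}, index=[f"c{i}" for i in range(len(act))])
        r = pd.DataFrame({"S": resp},
                         index=[f"c{i}" for i in range(len(resp))])
        return a, r

    def test_self_correlation(self):
        x = np.arange(8.0)
        a, r = self._tables(x, x.copy())
        res = csr.correlate(a, r)
        assert res.r.loc["P", "S"] == pytest.approx(1.0)
        assert res.p.loc["P", "S"] < 1e-6

    def test_affine_invariance(self):
        a, r = self._tables([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        res = csr.correlate(a, r)
        assert res.r.loc["P", "S"] == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 5.0])
        a, r = self._tables(x, y)
        res = csr.correlate(a, r)
        # independent evaluation of the Pearson formula + t transform
        xm, ym = x - x.mean(), y - y.mean()
        r_hand = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
        n = len(x)
        t = r_hand * np.sqrt((n - 2) / (1 - r_hand ** 2))
        p_hand = 2.0 * stats.t.sf(abs(t), df=n - 2)
        assert res.r.loc["P", "S"] == pytest.approx(r_hand, abs=1e-10)
        assert res.p.loc["P", "S"] == pytest.approx(p_hand, abs=1e-10)
        assert res.n.loc["P", "S"] == n

    def test_zero_variance_reported_missing(self):
        a, r = self._tables([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        res = csr.correlate(a, r)
        assert np.isnan(res.r.loc["P", "S"])

    def test_too_few_conditions_rejected(self):
        a, r = self._tables([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(csr.PipelineError, match=">= 3"):
            csr.correlate(a, r)

    def test_condition_subset_respected(self):
        x = np.arange(8.0)
        a, r = self._tables(x, x)
        res = csr.correlate(a, r, condition_subset=["c0", "c1", "c2", "c3"])
        assert res.n.loc["P", "S"] == 4


class TestRankSheddases:
    def _corr(self, r_vals, p_vals):
        prot = [f"P{i}" for i in range(len(r_vals))]
        r = pd.DataFrame({"S": r_vals}, index=prot)
        p = pd.DataFrame({"S": p_vals}, index=prot)
        n = pd.DataFrame({"S": [8] * len(prot)}, index=prot)
        return csr.CorrelationResult(r=r, p=p, n=n)

    def test_sorted_by_descending_r(self):
        corr = self._corr([0.2, 0.9, 0.5], [0.5, 0.01, 0.2])
        assert csr.rank_sheddases(corr, "S") == ["P1", "P2", "P0"]

    def test_tie_broken_by_p_then_label(self):
        corr = self._corr([0.5, 0.5, 0.5], [0.2, 0.1, 0.2])
        assert csr.rank_sheddases(corr, "S") == ["P1", "P0", "P2"]

    def test_single_defined_protease(self):
        corr = self._corr([np.nan, 0.4], [np.nan, 0.3])
        assert csr.rank_sheddases(corr, "S") == ["P1"]

    def test_all_undefined_errors(self):
        corr = self._corr([np.nan, np.nan], [np.nan, np.nan])
        with pytest.raises(csr.PipelineError, match="undefined"):
            csr.rank_sheddases(corr, "S")

    def test_generator_ground_truth_recovered(self):
        act = sd.gen_activities(21)
        shed, truth = sd.gen_shedding_panel(act, seed=22, noise_cv=0.10)
        resp = csr.normalize_responses(shed["raw"], shed["cell_counts"],
                                       shed["background"])
        mab = [c for c in act.index if c.endswith("+mAb")]
        corr = csr.correlate(act, resp, condition_subset=mab)
        assert csr.rank_sheddases(corr, "HB-EGF")[0] == "ADAM12"
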