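import numpy as np
import pandas as pd
import pytest

from tomarker.io import to_log10
from tomarker.preprocess import (
    PreprocessingError,
    correct_drift,
    drop_undetected,
    filter_features,
    impute_missing,
    pca_qc,
)
from tomarker.simulate import SimulationConfig, simulate_feature_table

from conftest import make_table


def _qc_slopes(table):
    qc_ids = table.injection_ids("qc")
    order = table.injections.loc[qc_ids, "injection_order"].to_numpy(float)
    log10 = np.log10(table.values[qc_ids].to_numpy())
    return np.array([np.polyfit(order, row, 1)[0] for row in log10])


def noise_free_drift(seed=11, slope_sd=0.005):
    return SimulationConfig(
        n_features=25, replicate_log10_sd=0.0, qc_log10_sd=0.0,
        drift_slope_log10_sd=slope_sd,
        marker_fraction_per_contrast=0.0, censor_log10_threshold=-np.inf, seed=seed,
    )


class TestDriftCorrection:
    def test_null_drift_is_identity(self):
        table, _ = simulate_feature_table(noise_free_drift(slope_sd=0.0))
        corrected, model = correct_drift(table)
        assert np.allclose(
            corrected.values.to_numpy(), table.values.to_numpy(), rtol=1e-9
        )
        assert np.allclose(model["slope"].to_numpy(float), 0.0, atol=1e-12)

    def test_slope_recovery_noise_free(self):
        """Injected 0.005/injection drift: post-correction QC slope < 1e-9."""
        table, truth = simulate_feature_table(noise_free_drift())
        corrected, model = correct_drift(table)
        assert np.allclose(
            model["slope"].to_numpy(float), truth.drift_slope.to_numpy(), atol=1e-9
        )
        assert np.max(np.abs(_qc_slopes(corrected))) < 1e-9

    def test_idempotent(self):
        table, _ = simulate_feature_table(noise_free_drift(seed=3))
        once, _ = correct_drift(table)
        _, model2 = correct_drift(once)
        assert np.max(np.abs(model2["slope"].to_numpy(float))) < 1e-9

    def test_single_anchor_feature_passed_through(self):
        """A feature present in only one QC cannot be fitted: flagged, untouched."""
        table = make_table(
            [[100.0, 104.0, 110.0, None, 120.0],
             [100.0, 105.0, 108.0, 112.0, 120.0]],
            sample_types=["sample", "qc", "sample", "qc", "sample"],
            groups=["DO", None, "D", None, "PF"],
        )
        corrected, model = correct_drift(table)
        assert not model.loc["F0", "corrected"]
        assert model.loc["F0", "n_anchor"] == 1
        present = ~table.missing.iloc[0].to_numpy()
        assert np.allclose(
            corrected.values.iloc[0].to_numpy()[present],
            table.values.iloc[0].to_numpy()[present],
        )
        assert model.loc["F1", "corrected"]

    def test_no_qc_directs_to_all_samples_anchor(self):
        table = make_table([[10.0, 12.0, 14.0]], groups=["DO", "DO", "D"])
        with pytest.raises(PreprocessingError, match="all_samples"):
            correct_drift(table, anchor="qc")
        corrected, model = correct_drift(table, anchor="all_samples")
        assert model.loc["F0", "corrected"]

    def test_missing_untouched(self, small_sim):
        _, table, _ = small_sim
        corrected, _ = correct_drift(drop_undetected(table))
        assert corrected.missing.equals(drop_undetected(table).missing)


class TestImputation:
    def test_no_missing_is_identity(self):
        table = make_table([[10.0, 20.0], [5.0, 8.0]])
        out = impute_missing(table, seed=0)
        assert out.values.equals(table.values)

    def test_bounds_and_present_unchanged(self):
        """Imputed draws fall strictly in (0, min/10]; present cells exact."""
        table = make_table([[5000.0, 9000.0, None, None, None]])
        for seed in range(200):
            out = impute_missing(table, seed=seed)
            imputed = out.values.iloc[0, 2:].to_numpy()
            assert np.all(imputed > 0) and np.all(imputed <= 500.0)
            assert out.values.iloc[0, 0] == 5000.0
            assert not out.missing.to_numpy().any()

    def test_determinism(self, small_sim):
        _, table, _ = small_sim
        table = drop_undetected(table)
        a = impute_missing(table, seed=7)
        b = impute_missing(table, seed=7)
        assert a.values.equals(b.values)

    def test_all_missing_feature_errors(self):
        table = make_table([[None, None], [1.0, 2.0]])
        with pytest.raises(PreprocessingError, match="F0"):
            impute_missing(table, seed=0)


class TestFiltering:
    def _table(self):
        # columns: 2 blanks, 2 QCs, 6 DO samples
        sample_types = ["blank"] * 2 + ["qc"] * 2 + ["sample"] * 6
        groups = [None] * 4 + ["DO"] * 6
        values = [
            [100, 100, 150, 150, 150, 150, 150, 150, 150, 150],  # blank ratio 1.5
            [None, None, 50, 50, 50, 50, 50, 50, 50, 50],        # clean, QC RSD 0
            [None, None, 40, 60, 50, 50, 50, 50, 50, 50],        # QC RSD 28%
            [None, None, 50, 50, 50, None, None, None, None, 50],  # detected 2/6
        ]
        return make_table(values, sample_types=sample_types, groups=groups)

    def test_reason_codes(self):
        table = self._table()
        kept, report = filter_features(table, blank_ratio_min=3.0,
                                       qc_rsd_max=30.0, detection_rate_min=0.5)
        assert report.loc["F0", "reasons"] == "blank_ratio"
        assert report.loc["F1", "kept"]
        assert report.loc["F2", "kept"]  # RSD ~28% passes at 30
        assert report.loc["F3", "reasons"] == "detection_rate"
        assert list(kept.features.index) == ["F1", "F2"]

    def test_zero_variance_qc_passes_any_threshold(self):
        table = self._table()
        _, report = filter_features(table, qc_rsd_max=0.0)
        assert "qc_rsd" not in report.loc["F1", "reasons"]

    def test_groupwise_detection_rule(self):
        """Present in 6/6 PF and 0/18 elsewhere is kept at rate 0.5."""
        sample_types = ["sample"] * 24
        groups = ["DO"] * 6 + ["D"] * 6 + ["PF"] * 6 + ["PS"] * 6
        row = [None] * 12 + [50.0] * 6 + [None] * 6
        table = make_table([row], sample_types=sample_types, groups=groups)
        _, report = filter_features(table, detection_rate_min=0.5)
        assert report.loc["F0", "kept"]

    def test_monotone_in_thresholds(self):
        table = self._table()
        kept_sizes = []
        for rsd_max in (50.0, 30.0, 10.0, 0.0):
            kept, _ = filter_features(table, qc_rsd_max=rsd_max)
            kept_sizes.append(kept.n_features)
        assert kept_sizes == sorted(kept_sizes, reverse=True)

    def test_no_blanks_skips_blank_filter(self):
        table = make_table(
            [[50.0] * 8],
            sample_types=["qc"] * 2 + ["sample"] * 6,
            groups=[None] * 2 + ["DO"] * 6,
        )
        _, report = filter_features(table)
        assert report.loc["F0", "kept"]


class TestPCA:
    def test_duplicate_injections_have_identical_scores(self):
        table = make_table(
            [[10.0, 10.0, 20.0], [7.0, 7.0, 9.0]],
            groups=["DO", "DO", "D"],
        )
        res = pca_qc(table)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[1])

    def test_rank_one_variance(self):
        """Only one feature varies: PC1 captures everything."""
        table = make_table(
            [[10.0, 100.0, 1000.0], [5.0, 5.0, 5.0]],
            groups=["DO", "D", "PF"],
        )
        res = pca_qc(table)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_missing_rejected(self):
        table = make_table([[1.0, None, 3.0]], groups=["DO", "D", "PF"])
        with pytest.raises(PreprocessingError, match="impute"):
            pca_qc(table)

    def test_variance_fractions_sorted_and_bounded(self, small_sim):
        _, table, _ = small_sim
        imputed = impute_missing(drop_undetected(table), seed=1)
        res = pca_qc(imputed)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_process_separates_on_pc1(self):
        """A dominant Process effect puts PS apart from the rest on PC1
        (positive mean silhouette over seeds)."""
        from sklearn.metrics import silhouette_score

        rng_groups = ["DO"] * 6 + ["D"] * 6 + ["PF"] * 6 + ["PS"] * 6
        sils = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = rng.uniform(4, 6, size=(40, 1))
            log10 = base + rng.normal(0, 0.15, size=(40, 24))
            log10[:30, 18:] += 1.0          # strong Process shift on PS samples
            log10[:5, :12] += 0.1           # weak datterini (Variety) effect
            table = make_table((10.0 ** log10).tolist(), groups=rng_groups)
            res = pca_qc(table)
            pc1 = res.scores["PC1"].to_numpy().reshape(-1, 1)
            is_ps = np.array([g == "PS" for g in rng_groups])
            sils.append(silhouette_score(pc1, is_ps))
        assert np.mean(sils) > 0
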