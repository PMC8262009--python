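"""Movement statistics S1-S16 and the residual matrix."""

import warnings

import numpy as np
import pandas as pd
import pytest

from movesynd.landscape import FOREST, LOGGER_ATTRIBUTES, MATRIX, OPEN, Datalogger
from movesynd.likelihood import NO_DETECTION, RELEASE, DetectionHistory
from movesynd.stats import (
    PARAM_COLUMNS,
    STAT_NAMES,
    compute_stats,
    residual_stats,
    stats_table,
    zscore_columns,
)


def logger(id, x, y, FC=0.5, OA=0.3, MA=0.2, HE=1.0, NN=0.0, PI=10, SO=20, CE=5):
    return Datalogger(id, x, y, 100.0, dict(FC=FC, OA=OA, MA=MA, HE=HE, NN=NN, PI=PI, SO=SO, CE=CE))


@pytest.fixture
def forest_open_pair():
    loggers = [
        logger("F", 0.0, 0.0, FC=0.9, OA=0.05, MA=0.05),
        logger("O", 300.0, 400.0, FC=0.1, OA=0.8, MA=0.1),
    ]
    habitat = np.array([FOREST, OPEN])
    return loggers, habitat


class TestComputeStats:
    def test_single_logger_repeated_detections(self, forest_open_pair):
        loggers, hab = forest_open_pair
        h = DetectionHistory("x", (0, 0), np.array([RELEASE, 0, 0, 0]))
        s = compute_stats(h, loggers, hab)
        assert s["S1"] == pytest.approx(0.9)
        assert s["S9"] == 1.0 and s["S10"] == 0.0
        assert s["S11"] == 0.0 and s["S12"] == 0.0 and s["S13"] == 0.0
        assert s["S14"] == 1 and s["S15"] == 1.0 and s["S16"] == 1.0

    def test_strict_alternation(self, forest_open_pair):
        loggers, hab = forest_open_pair
        obs = np.array([RELEASE] + [0, 1] * 5)
        h = DetectionHistory("x", (0, 0), obs)
        s = compute_stats(h, loggers, hab)
        assert s["S11"] == 1.0
        assert s["S14"] == 2 and s["S15"] == 0.5
        assert s["S9"] == 0.5 and s["S10"] == 0.5
        assert s["S12"] == pytest.approx(500.0)  # 300-400-500 triangle
        assert s["S16"] == 1.0

    def test_sparse_window_ratio(self, forest_open_pair):
        loggers, hab = forest_open_pair
        obs = np.full(16, NO_DETECTION)
        obs[0] = RELEASE
        det_slots = [2, 4, 5, 8, 10, 12, 14]  # 7 detections over a 13-slot window
        for t in det_slots:
            obs[t] = 0
        h = DetectionHistory("x", (0, 0), obs)
        s = compute_stats(h, loggers, hab)
        assert s["S16"] == pytest.approx(7 / 13)

    def test_single_detection_degeneracies(self, forest_open_pair):
        loggers, hab = forest_open_pair
        h = DetectionHistory("x", (0, 0), np.array([RELEASE, NO_DETECTION, 1]))
        s = compute_stats(h, loggers, hab)
        assert np.isnan(s["S11"]) and np.isnan(s["S12"])
        assert s["S13"] == 0.0 and s["S16"] == 1.0

    def test_attribute_means_are_detection_weighted(self, forest_open_pair):
        loggers, hab = forest_open_pair
        h = DetectionHistory("x", (0, 0), np.array([RELEASE, 0, 0, 1]))
        s = compute_stats(h, loggers, hab)
        assert s["S1"] == pytest.approx((0.9 + 0.9 + 0.1) / 3)
        assert s["S7"] == pytest.approx(20.0)

    def test_pigeonhole_bound_on_modal_share(self, forest_open_pair):
        loggers, hab = forest_open_pair
        rng = np.random.default_rng(0)
        for _ in range(30):
            obs = np.concatenate([[RELEASE], rng.integers(-1, 2, size=12)])
            if (obs >= 0).sum() == 0:
                continue
            s = compute_stats(DetectionHistory("x", (0, 0), obs), loggers, hab)
            assert s["S15"] >= 1.0 / s["S14"] - 1e-12

    def test_invariance_under_relabeling_and_translation(self, forest_open_pair):
        loggers, hab = forest_open_pair
        obs = np.array([RELEASE, 0, 1, NO_DETECTION, 0])
        s = compute_stats(DetectionHistory("x", (0, 0), obs), loggers, hab)
        swapped = [loggers[1], loggers[0]]
        obs2 = np.array([RELEASE, 1, 0, NO_DETECTION, 1])
        s2 = compute_stats(DetectionHistory("x", (0, 0), obs2), swapped, hab[::-1])
        pd.testing.assert_series_equal(s, s2)
        moved = [
            Datalogger(lg.id, lg.x + 5e3, lg.y - 2e3, lg.detect_radius_m, lg.attributes)
            for lg in loggers
        ]
        s3 = compute_stats(DetectionHistory("x", (5e3, -2e3), obs), moved, hab)
        pd.testing.assert_series_equal(s, s3)


class TestResidualMatrix:
    def _tables(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        obs = pd.DataFrame(
            rng.uniform(size=(n, 16)), columns=STAT_NAMES, index=[f"i{j}" for j in range(n)]
        )
        pred = obs + rng.normal(scale=0.1, size=(n, 16))
        theta = rng.normal(size=(n, 7))
        return obs, pred, theta

    def test_zero_residuals_when_prediction_is_exact(self):
        obs, _, theta = self._tables()
        raw = residual_stats(obs, obs.copy(), theta, normalize=False)
        assert np.allclose(raw[STAT_NAMES].to_numpy(), 0.0)
        assert list(raw.columns) == STAT_NAMES + PARAM_COLUMNS

    def test_zscoring_contract(self):
        obs, pred, theta = self._tables()
        z = residual_stats(obs, pred, theta)
        assert np.abs(z.mean(axis=0)).max() < 1e-10
        assert np.abs(z.var(axis=0, ddof=1) - 1.0).max() < 1e-10

    def test_zero_variance_column_dropped_with_warning(self):
        obs, pred, theta = self._tables()
        theta[:, 0] = 3.14  # constant D1 column
        with pytest.warns(UserWarning, match="zero-variance"):
            z = residual_stats(obs, pred, theta)
        assert "D1" not in z.columns

    def test_missing_stats_mean_imputed_to_zero(self):
        obs, pred, theta = self._tables()
        obs.loc["i0", "S11"] = np.nan  # single-detection individual
        z = residual_stats(obs, pred, theta)
        assert z.loc["i0", "S11"] == 0.0

    def test_param_columns_carry_transformed_theta(self):
        obs, pred, theta = self._tables()
        raw = residual_stats(obs, pred, theta, normalize=False)
        assert np.allclose(raw["K2"], theta[:, 3])
        assert np.allclose(raw["q"], theta[:, 6])
        assert np.allclose(raw["D1"], theta[:, 0])


class TestNullCalibration:
    def test_residuals_centre_on_zero_for_self_simulated_data(self, small_study):
        """Data simulated at known parameters, predictive at the same
        parameters: per-column mean |z| of the residuals stays small."""
        from movesynd.simulate import posterior_predictive

        study = small_study
        view = study.study_data(min_detections=1)
        keep = [i for i, h in enumerate(study.histories) if h.n_detections >= 1]

        class V:
            histories = view.histories
            loggers = study.loggers
            mesh = study.mesh
            logger_habitat = study.logger_habitat

        observed = stats_table(view.histories, study.loggers, study.logger_habitat)
        chains = study.true_theta[keep][None, :, :]
        _, per_ind = posterior_predictive(chains, V(), n_rep=150, seed=1, at="mean")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = residual_stats(observed, per_ind, study.true_theta[keep])
        resid_cols = [c for c in z.columns if c.startswith("S")]
        col_mean_abs = z[resid_cols].mean(axis=0).abs()
        assert col_mean_abs.mean() < 0.5
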