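"""Two-stage multi-output regressor stacking: scaling, degeneracies,
masking contract and whole-environment hold-out."""

import numpy as np
import pandas as pd
import pytest

from mtgp.bmors import fit_bmors, fit_bmors_env, scale_predictions
from mtgp.crossval import cv_random_part
from mtgp.data import PhenotypeTable, build_design
from mtgp.errors import DataValidationError
from mtgp.linalg import safe_cholesky
from mtgp.metrics import pearson
from mtgp.samplers import ChainSettings, PredictorComponent, fit_univariate
from mtgp.simulate import SimulationTruth, simulate_bmtme, _exchangeable

from helpers import structured_grm


def _settings(n_iter=800, burn_in=300, seed=0):
    return ChainSettings(n_iter=n_iter, burn_in=burn_in, thin=1, seed=seed)


class TestScalePredictions:
    def test_hand_computed_column(self):
        out = scale_predictions(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.zhat.ravel(), [-1.0, 0.0, 1.0])
        assert out.means[0] == 2.0 and out.sds[0] == 1.0

    def test_standardized_column_unchanged(self):
        col = np.array([-1.0, 0.0, 1.0])[:, None]
        out = scale_predictions(col)
        np.testing.assert_allclose(out.zhat, col, atol=1e-12)

    def test_zero_sd_names_trait(self):
        yhat = np.column_stack([np.ones(4), np.arange(4.0)])
        with pytest.raises(DataValidationError, match="PH"):
            scale_predictions(yhat, trait_names=["PH", "FL"])

    def test_columns_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        out = scale_predictions(rng.standard_normal((50, 4)) * 7 + 3)
        np.testing.assert_allclose(out.zhat.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(out.zhat.std(axis=0, ddof=1), 1.0, atol=1e-8)


def _single_trait_dataset(seed=0, J=60, I=2, h2=0.5):
    """Complete layout, one trait, genetic variance 1, residual (1-h2)/h2."""
    G = structured_grm(J, seed=seed)
    truth = SimulationTruth(
        beta_true=np.full((I, 1), 5.0),
        sigma_t_true=np.array([[1.0]]),
        sigma_e_true=0.5 * _exchangeable(I, 0.5),
        re_true=np.array([[(1.0 - h2) / h2]]),
        seed=seed + 700,
    )
    envs = [f"E{i + 1}" for i in range(I)]
    table = simulate_bmtme(G, envs, ["T1"], truth)
    d = build_design(table, G)
    comps = [PredictorComponent(d.X, "BRR", "Env"),
             PredictorComponent(d.Z1, "BRR", "Gen"),
             PredictorComponent(d.Z2, "BRR", "EnvGen")]
    return table, d, comps


class TestFitBmors:
    def test_single_trait_matches_plain_gblup(self):
        """With L=1, stage 2 regresses the trait on its own scaled stage-1
        prediction; testing accuracy stays within 0.1 of plain GBLUP."""
        table, d, comps = _single_trait_dataset(seed=1)
        Y = table.response_matrix()
        parts = cv_random_part(table, 5, 0.2, seed=2)
        st = _settings(seed=3)
        res = fit_bmors(Y, comps, st, parts, trait_names=["T1"],
                        env_labels=table.envs)
        stacked_mean = res.records["Pearson"].mean()
        plain = []
        for test_idx in parts.partitions:
            y = Y[:, 0].copy()
            y[test_idx] = np.nan
            fit = fit_univariate(y, comps, st)
            plain.append(pearson(Y[test_idx, 0], fit.yhat[test_idx]))
        assert abs(stacked_mean - np.mean(plain)) < 0.1

    def test_own_prediction_coefficient_positive(self):
        """The stage-2 coefficient on a trait's own scaled prediction is
        positive in >= 9/10 seeds for heritable simulated traits."""
        hits = 0
        for seed in range(10):
            G = structured_grm(60, seed=seed)
            truth = SimulationTruth(
                beta_true=np.tile([[2.0, 4.0]], (2, 1)),
                sigma_t_true=np.eye(2),
                sigma_e_true=0.5 * _exchangeable(2, 0.5),
                re_true=0.5 * np.eye(2),
                seed=seed + 40,
            )
            table = simulate_bmtme(G, ["E1", "E2"], ["A", "B"], truth)
            d = build_design(table, G)
            comps = [PredictorComponent(d.X, "BRR", "Env"),
                     PredictorComponent(d.Z1, "BRR", "Gen"),
                     PredictorComponent(d.Z2, "BRR", "EnvGen")]
            parts = cv_random_part(table, 1, 0.2, seed=seed)
            res = fit_bmors(table.response_matrix(), comps,
                            _settings(500, 200, seed), parts,
                            trait_names=["A", "B"])
            coefs = res.stage2_coefficients[0]
            hits += (coefs[0, 0] > 0) and (coefs[1, 1] > 0)
        assert hits >= 9

    def test_masked_values_never_read(self):
        table, d, comps = _single_trait_dataset(seed=4)
        Y = table.response_matrix()
        parts = cv_random_part(table, 1, 0.2, seed=5)
        st = _settings(300, 100, 6)
        a = fit_bmors(Y, comps, st, parts, env_labels=table.envs)
        Y2 = Y.copy()
        Y2[parts.partitions[0]] = -4242.0
        # metrics differ (observed values changed) but predictions are bitwise equal
        b = fit_bmors(Y2, comps, st, parts, env_labels=table.envs)
        for pa, pb in zip(a.predictions, b.predictions):
            np.testing.assert_array_equal(pa, pb)

    def test_single_partition_se_nan(self):
        table, d, comps = _single_trait_dataset(seed=7)
        parts = cv_random_part(table, 1, 0.2, seed=8)
        res = fit_bmors(table.response_matrix(), comps, _settings(300, 100, 9),
                        parts, env_labels=table.envs)
        assert res.summary["SE_Pearson"].isna().all()
        assert res.summary["SE_MAAPE"].isna().all()

    def test_unknown_cov_model_rejected(self):
        table, d, comps = _single_trait_dataset(seed=10)
        parts = cv_random_part(table, 1, 0.2, seed=0)
        with pytest.raises(DataValidationError, match="covModel"):
            fit_bmors(table.response_matrix(), comps, _settings(), parts,
                      cov_model="Ridge")


class TestFitBmorsEnv:
    def _three_env_table(self, seed=0):
        G = structured_grm(30, seed=seed)
        truth = SimulationTruth(
            beta_true=np.tile([[3.0, 6.0]], (3, 1)),
            sigma_t_true=_exchangeable(2, 0.5),
            sigma_e_true=_exchangeable(3, 0.6),
            re_true=0.5 * np.eye(2),
            seed=seed + 11,
        )
        table = simulate_bmtme(G, ["EBU", "KAK", "KTI"], ["A", "B"], truth)
        d = build_design(table, G)
        comps = [PredictorComponent(d.X, "BRR", "Env"),
                 PredictorComponent(d.Z1, "BRR", "Gen"),
                 PredictorComponent(d.Z2, "BRR", "EnvGen")]
        return table, comps

    def test_two_heldout_envs_give_2L_rows(self):
        table, comps = self._three_env_table()
        res = fit_bmors_env(table, ["KTI", "EBU"], comps,
                            settings=_settings(300, 100, 1))
        assert len(res.records) == 4  # 2 environments x 2 traits
        assert set(res.records["Environment"]) == {"KTI", "EBU"}
        assert res.summary["SE_Pearson"].isna().all()

    def test_duplicated_environment_transfer(self):
        """Holding out one of two identical environments: training on the
        duplicate gives high testing accuracy for a strongly heritable trait."""
        rng = np.random.default_rng(21)
        J, h2 = 60, 0.9
        G = structured_grm(J, seed=21)
        LG = safe_cholesky(G.values)
        b = rng.standard_normal((J, 2)) @ safe_cholesky(_exchangeable(2, 0.5)).T
        gv = LG @ b
        e = np.sqrt((1 - h2) / h2) * rng.standard_normal((J, 2))
        block = 5.0 + gv + e
        df = pd.DataFrame({
            "GID": list(G.line_ids) * 2,
            "Env": ["E1"] * J + ["E2"] * J,
            "A": np.tile(block[:, 0], 2),
            "B": np.tile(block[:, 1], 2),
        })
        table = PhenotypeTable(df, env_col="Env")
        d = build_design(table, G)
        comps = [PredictorComponent(d.X, "BRR", "Env"),
                 PredictorComponent(d.Z1, "BRR", "Gen"),
                 PredictorComponent(d.Z2, "BRR", "EnvGen")]
        res = fit_bmors_env(table, ["E2"], comps, settings=_settings(800, 300, 22))
        assert (res.records["Pearson"] > 0.8).all()

    def test_unknown_env_rejected(self):
        table, comps = self._three_env_table(seed=1)
        with pytest.raises(DataValidationError, match="unknown environment"):
            fit_bmors_env(table, ["XXX"], comps, settings=_settings())

    def test_all_envs_held_out_rejected(self):
        table, comps = self._three_env_table(seed=2)
        with pytest.raises(DataValidationError, match="proper subset"):
            fit_bmors_env(table, ["EBU", "KAK", "KTI"], comps,
                          settings=_settings())
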