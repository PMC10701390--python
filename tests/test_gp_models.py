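import numpy as np
import pandas as pd
import pytest

from sparsegp.gp_models import (
    MODEL_TERMS,
    McmcConfig,
    ModelError,
    build_grm,
    build_kernels,
    fit_gibbs,
    make_records,
    predict_missing,
    qc_filter,
)


class TestQcFilter:
    def test_monomorphic_dropped(self):
        raw = np.array([[0, 0.0], [0, 2], [0, 0], [0, 2]])
        qc = qc_filter(raw)
        assert qc.p == 1
        assert (0, "maf") in qc.dropped_markers or (0, "zero variance") in qc.dropped_markers

    def test_hand_enumerated_oracle(self):
        """4 RILs x 5 markers; survivors decided by hand."""
        nan = np.nan
        raw = np.array(
            [
                # miss%:  0    25    0    50    0
                # MAF:   0.5  0.5  0.01? 0.5  0.25
                [0.0, nan, 0.0, nan, 0.0],
                [2.0, 0.0, 0.0, nan, 0.0],
                [0.0, 2.0, 0.0, 0.0, 0.0],
                [2.0, 2.0, 0.0, 2.0, 2.0],
            ]
        )
        # marker 3 (index 2) is monomorphic -> MAF 0 < 0.03
        qc = qc_filter(raw, max_missing=0.20, min_maf=0.03)
        assert list(qc.kept) == [0, 4]
        reasons = dict(qc.dropped_markers)
        assert reasons[1] == "missingness"
        assert reasons[3] == "missingness"
        assert reasons[2] == "maf"

    def test_clean_matrix_fully_retained_and_standardized(self):
        rng = np.random.default_rng(0)
        raw = rng.choice([0.0, 2.0], size=(50, 20), p=[0.6, 0.4])
        qc = qc_filter(raw)
        assert qc.p == 20
        np.testing.assert_allclose(qc.X.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(qc.X.std(axis=0), 1.0, atol=1e-12)

    def test_all_dropped_raises(self):
        raw = np.zeros((4, 3))
        with pytest.raises(ModelError, match="dropped"):
            qc_filter(raw)


class TestBuildGrm:
    def test_trace_equals_n(self):
        rng = np.random.default_rng(1)
        qc = qc_filter(rng.choice([0.0, 2.0], size=(30, 40)))
        G = build_grm(qc.X)
        assert np.trace(G) / 30 == pytest.approx(1.0, rel=1e-12)

    def test_hand_linear_algebra_oracle(self):
        dosages = np.array([[0.0, 2.0], [2.0, 0.0], [2.0, 2.0]])
        mean = dosages.mean(axis=0)
        sd = dosages.std(axis=0)
        X = (dosages - mean) / sd
        G = build_grm(X)
        expected = X @ X.T / 2
        np.testing.assert_allclose(G, expected, rtol=1e-12)
        # spot-check one entry fully by hand: column values are
        # (-2/3, 4/3, 4/3)*3/sqrt(8) etc.; verify symmetry + diagonal
        assert G[0, 1] == pytest.approx((X[0] @ X[1]) / 2)

    def test_duplicated_rows(self):
        X = np.array([[1.0, -1.0], [1.0, -1.0], [-2.0, 2.0]])
        G = build_grm(X)
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_zero_markers_rejected(self):
        with pytest.raises(ModelError):
            build_grm(np.zeros((3, 0)))


@pytest.fixture()
def toy_records():
    rils = [f"r{i}" for i in range(10)]
    fams = ["A"] * 4 + ["B"] * 3 + ["C"] * 3
    envs = ["e1", "e2", "e3"]
    rng = np.random.default_rng(2)
    qc = qc_filter(rng.choice([0.0, 2.0], size=(10, 25)))
    G = build_grm(qc.X)
    return make_records(rils, fams, envs), G


class TestBuildKernels:
    def test_env_kernel_definition(self, toy_records):
        records, G = toy_records
        ks = build_kernels("M1", records, G)
        E = ks.matrices["E"]
        env = records["env_id"].to_numpy()
        for a in range(len(records)):
            for b in range(len(records)):
                assert E[a, b] == (1.0 if env[a] == env[b] else 0.0)

    def test_hadamard_brute_force_oracle(self, toy_records):
        records, G = toy_records
        ks = build_kernels("M3", records, G)
        GE = ks.matrices["GE"]
        env = records["env_id"].to_numpy()
        ril = records["ril_idx"].to_numpy()
        for a in range(30):
            for b in range(30):
                want = G[ril[a], ril[b]] if env[a] == env[b] else 0.0
                assert GE[a, b] == pytest.approx(want)

    def test_m1_has_three_structures(self, toy_records):
        records, G = toy_records
        ks = build_kernels("M1", records, G)
        assert ks.labels == MODEL_TERMS["M1"]
        assert len(ks.matrices) == 3

    def test_kernels_are_psd(self, toy_records):
        records, G = toy_records
        ks = build_kernels("M3", records, G)
        for label in ks.labels:
            d, _ = ks.eig(label)
            assert d.min() >= 0.0


class TestFitGibbs:
    def test_constant_response(self, toy_records):
        records, G = toy_records
        ks = build_kernels("M1", records, G)
        y = np.full(len(records), 7.0)
        fit = fit_gibbs(y, ks, McmcConfig(n_iter=600, burn_in=200, thin=2, seed=1))
        assert fit.mu == pytest.approx(7.0, abs=0.05)
        for t in fit.labels:
            assert np.abs(fit.effects[t]).max() < 0.2

    def test_burnin_validation(self):
        with pytest.raises(ModelError):
            McmcConfig(n_iter=100, burn_in=100)

    def test_closed_form_gblup_oracle(self):
        """Fixed variances, single kernel: posterior mean == ridge formula."""
        rng = np.random.default_rng(5)
        n = 50
        qc = qc_filter(rng.choice([0.0, 2.0], size=(n, 60)))
        G = build_grm(qc.X)
        records = make_records([f"r{i}" for i in range(n)], ["A"] * n, ["e1"])
        ks = build_kernels(["G"], records, G)
        s2u, s2e = 1.5, 1.0
        u_true = rng.multivariate_normal(np.zeros(n), s2u * (G + 1e-8 * np.eye(n)))
        y = 3.0 + u_true + rng.normal(0, np.sqrt(s2e), n)
        fit = fit_gibbs(
            y, ks,
            McmcConfig(n_iter=4000, burn_in=500, thin=1, seed=9),
            fixed_variances={"G": s2u, "resid": s2e},
        )
        lam = s2e / s2u
        expected = G @ np.linalg.solve(G + lam * np.eye(n), y - fit.mu)
        err = np.abs(fit.effects["G"] - expected)
        # MC standard error of the chain mean, padded for autocorrelation
        mc_se = np.sqrt(s2u) / np.sqrt(fit.n_retained / 10)
        assert err.max() < 3 * max(mc_se, 0.05)

    def test_conditional_mean_prediction_oracle(self):
        """Missing-cell predictions == joint-Gaussian conditional mean."""
        rng = np.random.default_rng(6)
        n_ril, J = 8, 3
        qc = qc_filter(rng.choice([0.0, 2.0], size=(n_ril, 30)))
        G = build_grm(qc.X)
        records = make_records(
            [f"r{i}" for i in range(n_ril)], ["A"] * 4 + ["B"] * 4,
            [f"e{j}" for j in range(J)],
        )
        ks = build_kernels(["G", "E"], records, G)
        s2 = {"G": 1.0, "E": 0.8, "resid": 0.5}
        n = len(records)
        C = s2["G"] * ks.matrices["G"] + s2["E"] * ks.matrices["E"]
        y_full = rng.multivariate_normal(np.zeros(n), C + s2["resid"] * np.eye(n))
        y = y_full.copy()
        mis = np.zeros(n, dtype=bool)
        mis[rng.choice(n, 6, replace=False)] = True
        y[mis] = np.nan
        fit = fit_gibbs(
            y, ks,
            McmcConfig(n_iter=6000, burn_in=1000, thin=1, seed=10),
            fixed_variances=s2,
            fit_intercept=False,
        )
        obs = ~mis
        Coo = C[np.ix_(obs, obs)] + s2["resid"] * np.eye(obs.sum())
        Cmo = C[np.ix_(mis, obs)]
        expected = Cmo @ np.linalg.solve(Coo, y_full[obs] - 0.0)
        err = np.abs(fit.yhat[mis] - expected)
        assert err.max() < 0.15  # ~3 MC SEs at this chain length

    def test_shift_invariance_exact(self, toy_records):
        records, G = toy_records
        ks = build_kernels("M2", records, G)
        rng = np.random.default_rng(11)
        y = rng.normal(size=len(records))
        y[5::7] = np.nan
        cfg = McmcConfig(n_iter=300, burn_in=100, thin=1, seed=3)
        fit_a = fit_gibbs(y, ks, cfg)
        fit_b = fit_gibbs(y + 100.0, ks, cfg)
        np.testing.assert_allclose(fit_b.yhat, fit_a.yhat + 100.0, atol=1e-8)

    def test_same_seed_reproducible(self, toy_records):
        records, G = toy_records
        ks = build_kernels("M1", records, G)
        rng = np.random.default_rng(12)
        y = rng.normal(size=len(records))
        cfg = McmcConfig(n_iter=300, burn_in=100, thin=1, seed=8)
        a = fit_gibbs(y, ks, cfg)
        b = fit_gibbs(y, ks, cfg)
        assert a.mu == b.mu
        np.testing.assert_array_equal(a.yhat, b.yhat)
        assert a.var_components == b.var_components

    def test_no_observations_rejected(self, toy_records):
        records, G = toy_records
        ks = build_kernels("M1", records, G)
        with pytest.raises(ModelError):
            fit_gibbs(np.full(len(records), np.nan), ks)


class TestPredictMissing:
    def test_observed_cell_equals_fitted_value(self, toy_records):
        records, G = toy_records
        ks = build_kernels("M1", records, G)
        rng = np.random.default_rng(13)
        y = rng.normal(size=len(records))
        fit = fit_gibbs(y, ks, McmcConfig(n_iter=300, burn_in=100, thin=1, seed=2))
        out = predict_missing(fit, [("r0", "e1")])
        pos = records.index[
            (records["ril_id"] == "r0") & (records["env_id"] == "e1")
        ][0]
        assert out["y_pred"].iloc[0] == pytest.approx(fit.yhat[pos])

    def test_unknown_cell_rejected(self, toy_records):
        records, G = toy_records
        ks = build_kernels("M1", records, G)
        y = np.random.default_rng(14).normal(size=len(records))
        fit = fit_gibbs(y, ks, McmcConfig(n_iter=200, burn_in=50, thin=1, seed=2))
        with pytest.raises(ModelError):
            predict_missing(fit, [("nope", "e1")])

    def test_record_order_invariance(self):
        """Permuting the record index leaves per-cell predictions unchanged
        (checked against the deterministic conditional-mean oracle)."""
        rng = np.random.default_rng(15)
        n_ril, J = 6, 2
        qc = qc_filter(rng.choice([0.0, 2.0], size=(n_ril, 25)))
        G = build_grm(qc.X)
        records = make_records(
            [f"r{i}" for i in range(n_ril)], ["A"] * 3 + ["B"] * 3, ["e0", "e1"]
        )
        perm = rng.permutation(len(records))
        rec_b = records.iloc[perm].reset_index(drop=True)
        s2 = {"G": 1.2, "resid": 0.6}
        y = rng.normal(size=len(records))
        y[[1, 4, 7]] = np.nan
        cfg = McmcConfig(n_iter=5000, burn_in=1000, thin=1, seed=4)
        fit_a = fit_gibbs(y, build_kernels(["G"], records, G), cfg,
                          fixed_variances=s2, fit_intercept=False)
        fit_b = fit_gibbs(y[perm], build_kernels(["G"], rec_b, G), cfg,
                          fixed_variances=s2, fit_intercept=False)
        pred_a = predict_missing(fit_a, [("r0", "e1"), ("r2", "e0")])
        pred_b = predict_missing(fit_b, [("r0", "e1"), ("r2", "e0")])
        np.testing.assert_allclose(
            pred_a["y_pred"], pred_b["y_pred"], atol=0.12
        )
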