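"""Eyring conversion, BRR posterior, LOO scoring and forward selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chelate.modeling import (
    GAS_CONSTANT_KCAL,
    adjusted_r2,
    brr_fit,
    ddg_to_ee,
    ee_to_ddg,
    forward_select,
    loo_predictions,
    loo_scores,
    read_screening_table,
)


class TestEyring:
    def test_zero_ee_zero_energy(self):
        assert ee_to_ddg(0.0, 298.15) == 0.0
        assert ee_to_ddg(0.0, 77.0) == 0.0

    def test_reference_value(self):
        # R T ln(19) at 298.15 K
        assert ee_to_ddg(0.90, 298.15) == pytest.approx(1.745, abs=1e-3)
        assert ee_to_ddg(0.90, 298.15) == pytest.approx(
            GAS_CONSTANT_KCAL * 298.15 * np.log(19.0), rel=1e-12
        )

    @pytest.mark.parametrize("ee", [-0.999, -0.5, 0.0, 0.3, 0.95])
    def test_roundtrip_identity(self, ee):
        for t in (195.0, 298.15, 373.0):
            assert ddg_to_ee(ee_to_ddg(ee, t), t) == pytest.approx(ee, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        ee=st.floats(-0.999999, 0.999999),
        t=st.floats(1.0, 1000.0),
    )
    def test_roundtrip_property(self, ee, t):
        assert ddg_to_ee(ee_to_ddg(ee, t), t) == pytest.approx(ee, abs=1e-9)
        # sign of the energy difference follows the sign of the excess
        # (below ~1e-16 the 1 +/- ee rounding absorbs the excess entirely)
        if abs(ee) > 1e-12:
            assert np.sign(ee_to_ddg(ee, t)) == np.sign(ee)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ee_to_ddg(1.0, 298.15)
        with pytest.raises(ValueError):
            ee_to_ddg(0.5, -10.0)

    def test_screening_table_both_layouts(self, tmp_path):
        p1 = tmp_path / "ee.csv"
        p1.write_text("ligand_id,ee,temperature_K\nL1,0.90,298.15\nL2,-0.5,273\n")
        t1 = read_screening_table(p1)
        assert t1.loc["L1", "ddg"] == pytest.approx(1.745, abs=1e-3)
        p2 = tmp_path / "ddg.csv"
        p2.write_text("ligand_id,ddg_kcal_mol\nL1,1.745\n")
        assert read_screening_table(p2).loc["L1", "ddg"] == 1.745


class TestBRR:
    def test_noise_free_recovers_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 1))
        y = 3.0 * x[:, 0] + 1.0
        m = brr_fit(x, y)
        assert m.weights_raw[0] == pytest.approx(3.0, abs=1e-6)
        _, sd = m.predict(x, return_std=True)
        assert sd.max() < 1e-2

    def test_frozen_precisions_match_ridge_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(0, 0.3, 25)
        alpha, lam = 2.5, 7.0
        m = brr_fit(X, y, alpha=alpha, beta=lam)
        Z = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        A = alpha * np.eye(3) + lam * Z.T @ Z
        ridge = lam * np.linalg.solve(A, Z.T @ yc)
        np.testing.assert_allclose(m.weights, ridge, atol=1e-8)
        np.testing.assert_allclose(m.weight_cov, np.linalg.inv(A), atol=1e-8)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 2))
        y = X @ [1.0, 0.5] + rng.normal(0, 0.2, 30)
        m0 = brr_fit(X, y)
        perm = rng.permutation(30)
        m1 = brr_fit(X[perm], y[perm])
        np.testing.assert_allclose(m0.weights, m1.weights, atol=1e-10)
        np.testing.assert_allclose(m0.alpha, m1.alpha, rtol=1e-9)

    def test_predictive_variance_geometry(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = X @ [1.0, -1.0] + rng.normal(0, 0.3, 30)
        m = brr_fit(X, y)
        grid = np.linspace(-3, 3, 21)
        line = np.stack([m.x_mean + t * np.array([1.0, 0.4]) for t in grid])
        _, sd = m.predict(line, return_std=True)
        assert np.argmin(sd) == 10  # the training mean
        assert np.all(sd**2 >= 1.0 / m.beta - 1e-12)

    def test_predictive_coverage_near_one_sigma(self):
        # ~68% of held-out truths within mu +/- sigma on simulated data
        rng = np.random.default_rng(4)
        hits, total = 0, 0
        for _ in range(60):
            X = rng.normal(size=(30, 2))
            w = rng.normal(size=2)
            y = X @ w + 0.5 + rng.normal(0, 0.3, 30)
            m = brr_fit(X[:20], y[:20])
            mu, sd = m.predict(X[20:], return_std=True)
            hits += int(np.sum(np.abs(y[20:] - mu) <= sd))
            total += 10
        cover = hits / total
        # binomial 3 sigma around 0.6827 for n = 600
        assert abs(cover - 0.6827) < 3 * np.sqrt(0.6827 * 0.3173 / total) + 0.02

    def test_dimension_mismatch(self):
        m = brr_fit(np.eye(4), np.arange(4.0))
        with pytest.raises(ValueError):
            m.predict(np.ones((1, 3)))


class TestAdjustedR2:
    def test_perfect_prediction(self):
        y = np.arange(10.0)
        assert adjusted_r2(y, y, 3) == 1.0

    def test_worked_value(self):
        # R2 = 0.8, n = 20, p = 3 -> 1 - 0.2 * 19/16
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        ss_tot = ((y - y.mean()) ** 2).sum()
        resid = rng.normal(size=20)
        resid *= np.sqrt(0.2 * ss_tot / (resid**2).sum())
        assert adjusted_r2(y, y - resid, 3) == pytest.approx(0.7625, abs=1e-12)

    def test_monotone_penalty_in_p(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=15)
        yhat = y + rng.normal(0, 0.3, 15)
        vals = [adjusted_r2(y, yhat, p) for p in range(1, 6)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            adjusted_r2(np.arange(4.0), np.arange(4.0), 3)


class TestLOO:
    def test_matches_naive_refit_loop(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(18, 3))
        y = X @ [2.0, 0.0, -1.0] + rng.normal(0, 0.2, 18)
        fast = loo_predictions(X, y)
        naive = np.empty(18)
        for i in range(18):
            keep = np.arange(18) != i
            naive[i] = brr_fit(X[keep], y[keep]).predict(X[i : i + 1])[0]
        np.testing.assert_allclose(fast, naive, atol=1e-5)

    def test_noise_free_linear_scores(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 2))
        y = X @ [1.0, -0.5] + 2.0
        r2, mae = loo_scores(X, y)
        assert r2 > 0.999
        assert mae < 1e-3

    def test_loo_mae_exceeds_training_mae_on_average(self):
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(100):
            X = rng.normal(size=(20, 2))
            y = X @ rng.normal(size=2) + rng.normal(0, 0.3, 20)
            m = brr_fit(X, y)
            train_mae = np.mean(np.abs(y - m.predict(X)))
            _, loo_mae = loo_scores(X, y)
            diffs.append(loo_mae - train_mae)
        assert np.mean(diffs) > 0


def _exhaustive_best(frame, y, max_p):
    best = None
    for p in range(1, max_p + 1):
        for sub in itertools.combinations(frame.columns, p):
            try:
                r2, mae = loo_scores(frame[list(sub)].to_numpy(), y, p=p)
            except ValueError:
                continue
            key = (-r2, p, mae, tuple(sorted(sub)))
            if best is None or key < best[0]:
                best = (key, set(sub))
    return best[1]


class TestForwardSelect:
    def test_depth_one_equals_exhaustive_single_feature(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame(rng.normal(size=(20, 9)), columns=[f"f{i}" for i in range(9)])
        y = (1.5 * frame["f4"] + rng.normal(0, 0.2, 20)).to_numpy()
        top = forward_select(frame, y, max_features=1, top_k=1)[0]
        assert set(top.features) == _exhaustive_best(frame, y, 1)

    def test_full_beam_equals_exhaustive_small_instance(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(rng.normal(size=(22, 8)), columns=[f"f{i}" for i in range(8)])
        y = (frame["f1"] - 0.8 * frame["f6"] + rng.normal(0, 0.15, 22)).to_numpy()
        top = forward_select(frame, y, max_features=3, beam=len(frame.columns), top_k=1)[0]
        assert set(top.features) == _exhaustive_best(frame, y, 3)

    def test_duplicate_feature_never_added(self):
        rng = np.random.default_rng(10)
        frame = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        frame["a_copy"] = frame["a"]
        y = (2 * frame["a"] + rng.normal(0, 0.05, 20)).to_numpy()
        for rep in forward_select(frame, y, top_k=None):
            assert not {"a", "a_copy"} <= set(rep.features)

    def test_model_size_cap(self):
        rng = np.random.default_rng(11)
        frame = pd.DataFrame(rng.normal(size=(30, 15)), columns=[f"f{i}" for i in range(15)])
        y = rng.normal(size=30)
        for rep in forward_select(frame, y, top_k=None):
            assert len(rep.features) <= 3

    def test_zero_noise_recovers_planted_pair_exactly(self):
        rng = np.random.default_rng(12)
        frame = pd.DataFrame(rng.normal(size=(25, 52)), columns=[f"f{i}" for i in range(52)])
        y = (2.0 * frame["f7"] - frame["f19"]).to_numpy()
        top = forward_select(frame, y, top_k=1)[0]
        assert set(top.features) == {"f7", "f19"}

    def test_normalized_weights_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(13)
        frame = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        y = (1.2 * frame["a"] - 0.5 * frame["c"] + rng.normal(0, 0.1, 25)).to_numpy()
        r0 = forward_select(frame, y, top_k=1)[0]
        scaled = frame.copy()
        scaled["a"] = scaled["a"] * 1000.0  # e.g. different raw units
        r1 = forward_select(scaled, y, top_k=1)[0]
        assert r0.features == r1.features
        np.testing.assert_allclose(r0.normalized_weights, r1.normalized_weights, atol=1e-6)

    def test_small_sample_guard(self):
        frame = pd.DataFrame(np.random.default_rng(14).normal(size=(4, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="at least 6"):
            forward_select(frame, np.arange(4.0))
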