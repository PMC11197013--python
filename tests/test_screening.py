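"""Expected improvement and the pool-based BO loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from chelate.modeling import brr_fit
from chelate.screening import (
    AcquisitionTrace,
    bo_loop,
    bo_step,
    expected_improvement,
    retrospective_replay,
)


def ei_quadrature(mu, sigma, best):
    """Independent oracle: E[max(0, Y - best)] by numerical integration."""
    f = lambda t: max(t - best, 0.0) * norm.pdf(t, loc=mu, scale=sigma)
    lo, hi = mu - 12 * sigma, mu + 12 * sigma
    val, _ = quad(f, max(lo, best), hi, limit=200)
    return val


class TestExpectedImprovement:
    def test_deterministic_limit(self):
        assert expected_improvement(2.0, 0.0, 1.0) == 1.0
        assert expected_improvement(0.5, 0.0, 1.0) == 0.0

    def test_at_incumbent_unit_sigma(self):
        assert expected_improvement(1.0, 1.0, 1.0) == pytest.approx(0.398942, abs=1e-6)

    @pytest.mark.parametrize("mu", [-2.0, -0.3, 0.0, 0.7, 3.0])
    @pytest.mark.parametrize("sigma", [0.05, 0.5, 1.0, 2.5])
    def test_closed_form_matches_quadrature(self, mu, sigma):
        for best in (-1.0, 0.0, 1.5):
            assert expected_improvement(mu, sigma, best) == pytest.approx(
                ei_quadrature(mu, sigma, best), abs=1e-8
            )

    def test_monotone_in_mu_and_sigma(self):
        mus = np.linspace(-3, 3, 41)
        ei_mu = expected_improvement(mus, 0.8, 0.0)
        assert np.all(np.diff(ei_mu) > 0)
        sigmas = np.linspace(0.01, 3, 41)
        ei_sig = expected_improvement(-0.5, sigmas, 0.0)  # mu <= best
        assert np.all(np.diff(ei_sig) > 0)

    def test_continuity_at_sigma_zero(self):
        for mu, best in ((0.5, 0.0), (-0.5, 0.0), (0.0, 0.0)):
            lim = max(mu - best, 0.0)
            for s in 10.0 ** -np.arange(3, 10):
                assert abs(expected_improvement(mu, s, best) - lim) < 1e-2 * max(s ** 0.5, 1e-4) + 1e-3

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            expected_improvement(0.0, -1.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        mu=st.floats(-50, 50),
        sigma=st.floats(0, 20),
        best=st.floats(-50, 50),
    )
    def test_ei_dominates_deterministic_improvement(self, mu, sigma, best):
        ei = expected_improvement(mu, sigma, best)
        assert ei >= max(mu - best, 0.0) - 1e-9
        assert ei >= 0.0


def _toy_pool(n=20, seed=0, p=5):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=[f"g{i}" for i in range(p)],
        index=[f"L{i:02d}" for i in range(n)],
    )
    truth = 1.0 + 1.5 * frame["g1"] - 0.5 * frame["g3"] + rng.normal(0, 0.05, n)
    return frame, pd.Series(truth, index=frame.index)


class TestBOStep:
    def test_argmax_and_determinism(self):
        frame, truth = _toy_pool()
        ids = list(frame.index[:6])
        model = brr_fit(frame.loc[ids, ["g1", "g3"]].to_numpy(),
                        truth[ids].to_numpy(), feature_names=["g1", "g3"])
        best = truth[ids].max()
        c1, s1 = bo_step(model, frame, set(ids), best)
        c2, s2 = bo_step(model, frame, set(ids), best)
        assert c1 == c2
        pd.testing.assert_frame_equal(s1, s2)
        assert s1.loc[c1, "ei"] == s1["ei"].max()
        assert (s1["ei"] >= 0).all()

    def test_empty_pool_rejected(self):
        frame, truth = _toy_pool(n=4)
        model = brr_fit(frame[["g1"]].to_numpy(), truth.to_numpy(), feature_names=["g1"])
        with pytest.raises(ValueError, match="unacquired"):
            bo_step(model, frame, set(frame.index), truth.max())


class TestBOLoop:
    def test_initial_optimum_stops_quickly(self):
        # noise-free truth, initial batch holds the three best ligands and
        # every other candidate sits far below: EI collapses immediately
        rng = np.random.default_rng(3)
        g1 = np.concatenate([[5.0, 4.8, 4.6], rng.uniform(-3, -1, 12)])
        frame = pd.DataFrame(
            {"g1": g1, "g2": rng.normal(size=15)},
            index=[f"L{i:02d}" for i in range(15)],
        )
        truth = pd.Series(2.0 * frame["g1"], index=frame.index)
        initial = {i: float(truth[i]) for i in frame.index[:3]}
        tr = bo_loop(initial, frame, truth.to_dict())
        assert len(tr.steps) <= 1
        assert tr.stop_reason in {"converged", "pool_exhausted"}

    def test_infinite_epsilon_acquires_nothing(self):
        frame, truth = _toy_pool(n=12, seed=4)
        initial = {i: float(truth[i]) for i in frame.index[:3]}
        tr = bo_loop(initial, frame, truth.to_dict(), stop_epsilon=np.inf)
        assert tr.steps == []
        assert tr.stop_reason == "converged"

    def test_zero_epsilon_exhausts_pool(self):
        frame, truth = _toy_pool(n=10, seed=5)
        initial = {i: float(truth[i]) for i in frame.index[:3]}
        tr = bo_loop(initial, frame, truth.to_dict(), stop_epsilon=0.0)
        assert tr.stop_reason == "pool_exhausted"
        assert len(tr.steps) == 7
        assert len(set(tr.acquired_ids)) == 7  # each ligand acquired once

    def test_best_trace_non_decreasing(self):
        frame, truth = _toy_pool(n=25, seed=6)
        initial = {i: float(truth[i]) for i in frame.index[:3]}
        tr = bo_loop(initial, frame, truth.to_dict(), stop_epsilon=0.0, max_steps=15)
        bt = tr.best_trace
        assert all(a <= b + 1e-12 for a, b in zip(bt, bt[1:]))
        assert len(tr.steps) <= len(frame)

    def test_missing_oracle_entry_raises(self):
        frame, truth = _toy_pool(n=8, seed=7)
        initial = {i: float(truth[i]) for i in frame.index[:3]}
        partial = truth.iloc[:4].to_dict()
        with pytest.raises(KeyError, match="oracle"):
            bo_loop(initial, frame, partial, stop_epsilon=0.0)

    def test_fixed_feature_mode(self):
        frame, truth = _toy_pool(n=18, seed=8)
        initial = {i: float(truth[i]) for i in frame.index[:5]}
        tr = bo_loop(initial, frame, truth.to_dict(), refit_selection=False,
                     stop_epsilon=0.0, max_steps=4)
        feats = {tuple(s.features) for s in tr.steps}
        assert len(feats) == 1  # features frozen after the first selection

    def test_trace_frame_layout(self):
        frame, truth = _toy_pool(n=10, seed=9)
        initial = {i: float(truth[i]) for i in frame.index[:3]}
        tr = bo_loop(initial, frame, truth.to_dict(), stop_epsilon=0.0, max_steps=3)
        df = tr.to_frame()
        assert list(df.columns) == ["step", "ligand_id", "mu", "sigma", "ei",
                                    "observed", "best_after"]
        assert len(df) == 3


class TestReplay:
    def test_best_first_in_history_is_bounded(self):
        frame, truth = _toy_pool(n=12, seed=10)
        order = truth.sort_values(ascending=False).index
        records = pd.DataFrame({"ddg": truth[order]})
        rep = retrospective_replay(records, frame, stop_epsilon=0.0, max_steps=9)
        assert rep.historical_position == 1
        assert rep.bo_position == 0  # optimum inside the initial batch
        assert rep.bo_total_experiments >= 3

    def test_trace_never_longer_than_pool(self):
        frame, truth = _toy_pool(n=12, seed=11)
        records = pd.DataFrame({"ddg": truth})
        rep = retrospective_replay(records, frame, stop_epsilon=0.0)
        assert len(rep.trace.steps) <= len(frame)
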