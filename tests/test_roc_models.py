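"""Tests for DPSD/UVSD response probabilities, likelihood, fitting and
model selection."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from memroc import roc_models as rm

from conftest import CRITERIA


def _random_params(draw_floats):
    ro, dprime, vo = draw_floats
    gaps = np.array([0.3, 0.4, 0.5, 0.6])
    criteria = tuple(-1.0 + np.concatenate(([0.0], np.cumsum(gaps))))
    return (
        rm.DPSDParams(ro=ro, dprime=dprime, criteria=criteria),
        rm.UVSDParams(dprime=dprime, vo=vo, criteria=criteria),
    )


class TestResponseProbs:
    def test_null_dpsd_old_row_equals_new_row(self):
        p = rm.dpsd_response_probs(rm.DPSDParams(0.0, 0.0, CRITERIA))
        assert np.allclose(p[0], p[1])

    def test_ceiling_recollection_loads_top_bin(self):
        p = rm.dpsd_response_probs(rm.DPSDParams(1.0, 0.5, CRITERIA))
        assert p[0, -1] == pytest.approx(1.0)

    def test_null_uvsd_old_row_equals_new_row(self):
        p = rm.uvsd_response_probs(rm.UVSDParams(0.0, 1.0, CRITERIA))
        assert np.allclose(p[0], p[1])

    def test_evsd_reduction(self):
        d = rm.dpsd_response_probs(rm.DPSDParams(0.0, 0.8, CRITERIA))
        u = rm.uvsd_response_probs(rm.UVSDParams(0.8, 1.0, CRITERIA))
        assert np.allclose(d, u)

    @pytest.mark.parametrize(
        "maker,params",
        [
            (rm.dpsd_response_probs, rm.DPSDParams(0.3, 1.0, (-1, -0.5, 0, 0.5, 1))),
            (rm.uvsd_response_probs, rm.UVSDParams(1.2, 1.4, (-1, -0.5, 0, 0.5, 1))),
        ],
    )
    def test_monte_carlo_oracle(self, maker, params):
        """Closed-form bin probabilities match a 10^6-draw observer."""
        rng = np.random.default_rng(17)
        n = 10**6
        c = np.asarray(params.criteria)
        if isinstance(params, rm.DPSDParams):
            fam = params.dprime + rng.standard_normal(n)
            rec = rng.uniform(size=n) < params.ro
            resp = np.searchsorted(c, fam) + 1
            resp[rec] = 6
        else:
            strength = params.dprime + params.vo * rng.standard_normal(n)
            resp = np.searchsorted(c, strength) + 1
        emp_old = np.bincount(resp, minlength=7)[1:] / n
        new = np.searchsorted(c, rng.standard_normal(n)) + 1
        emp_new = np.bincount(new, minlength=7)[1:] / n
        pred = maker(params)
        assert np.abs(emp_old - pred[0]).max() < 0.005
        assert np.abs(emp_new - pred[1]).max() < 0.005

    @given(
        ro=st.floats(0.0, 1.0),
        dprime=st.floats(0.0, 3.0),
        vo=st.floats(0.2, 3.0),
    )
    def test_rows_are_probability_distributions(self, ro, dprime, vo):
        for p in _random_params((ro, dprime, vo)):
            table = rm.response_probs(p)
            assert np.all(table >= 0)
            assert np.allclose(table.sum(axis=1), 1.0)

    def test_unordered_criteria_raise(self):
        with pytest.raises(ValueError):
            rm.DPSDParams(0.3, 1.0, (0.5, 0.2, 1.0, 1.5, 2.0))


class TestGStatistic:
    def test_perfect_fit_is_zero(self):
        o = np.array([[10.0, 20.0, 30.0]])
        assert rm.g_statistic(o, o) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        o = np.array([10.0, 20.0, 30.0])
        e = np.array([20.0, 20.0, 20.0])
        expected = 2 * (10 * np.log(0.5) + 30 * np.log(1.5))
        assert rm.g_statistic(o, e) == pytest.approx(expected)
        assert expected == pytest.approx(10.46, abs=0.01)

    def test_zero_observed_cells_contribute_nothing(self):
        assert rm.g_statistic(
            np.array([0.0, 30.0]), np.array([5.0, 30.0])
        ) == pytest.approx(0.0)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            rm.g_statistic(np.array([-1.0]), np.array([1.0]))


class TestFitModel:
    def test_self_consistency_parameter_recovery(self):
        """Fitting expected counts of known parameters recovers them."""
        true = rm.DPSDParams(0.3, 1.0, CRITERIA)
        probs = rm.dpsd_response_probs(true)
        counts = np.round(probs * 10**5)
        fit = rm.fit_model(counts, "DPSD")
        assert fit.params.ro == pytest.approx(0.3, abs=0.02)
        assert fit.params.dprime == pytest.approx(1.0, abs=0.05)
        assert fit.g < 0.5
        assert fit.converged

    def test_chance_observer_null_recovery(self):
        rng = np.random.default_rng(9)
        chance = rm.dpsd_response_probs(rm.DPSDParams(0.0, 0.0, CRITERIA))
        counts = np.vstack(
            [rng.multinomial(5000, chance[0]), rng.multinomial(5000, chance[1])]
        )
        fit = rm.fit_model(counts, "DPSD")
        assert fit.params.ro < 0.05
        assert fit.params.dprime < 0.1

    def test_dpsd_data_prefer_dpsd_at_large_n(self):
        """UVSD mimics DPSD data but loses the BIC race when Ro > 0."""
        rng = np.random.default_rng(13)
        probs = rm.dpsd_response_probs(rm.DPSDParams(0.3, 1.0, CRITERIA))
        counts = np.vstack(
            [rng.multinomial(20000, probs[0]), rng.multinomial(20000, probs[1])]
        )
        d = rm.fit_model(counts, "DPSD")
        u = rm.fit_model(counts, "UVSD")
        assert u.params.vo > 1.0  # the mimicry channel
        assert d.bic < u.bic

    def test_bic_identity_and_df(self):
        rng = np.random.default_rng(2)
        probs = rm.dpsd_response_probs(rm.DPSDParams(0.2, 1.0, CRITERIA))
        counts = np.vstack(
            [rng.multinomial(180, probs[0]), rng.multinomial(180, probs[1])]
        )
        fit = rm.fit_model(counts, "DPSD")
        assert fit.n_params == 7
        assert fit.df == 3
        assert fit.bic == pytest.approx(
            -2 * fit.logL + fit.n_params * np.log(fit.n_trials)
        )

    def test_ml_dominance_over_true_parameters(self):
        rng = np.random.default_rng(31)
        true = rm.DPSDParams(0.25, 1.2, CRITERIA)
        probs = rm.dpsd_response_probs(true)
        for _ in range(5):
            counts = np.vstack(
                [rng.multinomial(300, probs[0]), rng.multinomial(300, probs[1])]
            )
            fit = rm.fit_model(counts, "DPSD")
            assert fit.logL >= rm.log_likelihood(true, counts) - 1e-6

    def test_evsd_likelihood_equivalence(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 40, size=(2, 6)).astype(float) + 1
        d = rm.log_likelihood(rm.DPSDParams(0.0, 0.9, CRITERIA), counts)
        u = rm.log_likelihood(rm.UVSDParams(0.9, 1.0, CRITERIA), counts)
        assert d == pytest.approx(u, abs=1e-8)

    def test_degenerate_counts_flagged_not_thrown(self):
        counts = np.array([[0, 0, 0, 0, 0, 50], [50, 0, 0, 0, 0, 0]])
        fit = rm.fit_model(counts, "DPSD")
        assert not fit.converged

    def test_high_ro_fit_yields_asymmetric_roc(self):
        """zROC slope < 1 for a recollection-heavy observer."""
        from memroc import descriptives as de

        probs = rm.dpsd_response_probs(rm.DPSDParams(0.5, 0.8, CRITERIA))
        counts = np.round(probs * 10**5)
        zf, zh = de.z_transform(de.roc_points(counts))
        slope = np.polyfit(zf, zh, 1)[0]
        assert slope < 1.0


def _fit_like(model, bic, p):
    probs_params = (
        rm.DPSDParams(0.2, 1.0, CRITERIA)
        if model == "DPSD"
        else rm.UVSDParams(1.0, 1.2, CRITERIA)
    )
    return rm.FitResult(
        model=model, params=probs_params, logL=-100.0, g=1.0, df=3, p=p,
        bic=bic, n_params=7, n_trials=360, converged=True, n_restarts_used=1,
    )


class TestSelectWinningModel:
    def test_unanimous_winner(self):
        pairs = [(_fit_like("DPSD", 210.0, 0.5), _fit_like("UVSD", 200.0, 0.5))] * 10
        assert rm.select_winning_model(pairs).winner == "UVSD"

    def test_sixty_percent_is_inconclusive(self):
        pairs = [
            (_fit_like("DPSD", 200.0, 0.5), _fit_like("UVSD", 210.0, 0.5))
        ] * 6 + [(_fit_like("DPSD", 210.0, 0.5), _fit_like("UVSD", 200.0, 0.5))] * 4
        assert rm.select_winning_model(pairs).winner == "inconclusive"

    def test_bic_win_without_acceptable_fit_is_inconclusive(self):
        good = (_fit_like("DPSD", 200.0, 0.5), _fit_like("UVSD", 210.0, 0.5))
        bad_fit = (_fit_like("DPSD", 200.0, 0.01), _fit_like("UVSD", 210.0, 0.5))
        pairs = [good] * 14 + [bad_fit] * 6  # 100% BIC wins, 70% acceptable G
        assert rm.select_winning_model(pairs).winner == "inconclusive"

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            rm.select_winning_model([])
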