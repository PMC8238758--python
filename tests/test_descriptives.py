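"""Tests for corrected rates, d', binning, exclusion, ROC points and AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from memroc import descriptives as de
from memroc import synthetic as syn

from conftest import CRITERIA


class TestCorrectedRates:
    def test_hand_arithmetic_of_the_correction(self):
        hr, far = de.corrected_rates(10, 10, 0, 10)
        assert hr == pytest.approx(10.5 / 11)
        assert far == pytest.approx(0.5 / 11)

    def test_symmetric_midpoint_is_fixed(self):
        assert de.corrected_rates(5, 10, 5, 10) == (0.5, 0.5)

    def test_impossible_counts_raise(self):
        with pytest.raises(ValueError):
            de.corrected_rates(11, 10, 0, 10)

    @given(
        n_old=st.integers(1, 500),
        n_new=st.integers(1, 500),
        data=st.data(),
    )
    def test_correction_maps_into_open_interval_and_is_monotone(
        self, n_old, n_new, data
    ):
        hits = data.draw(st.integers(0, n_old))
        fas = data.draw(st.integers(0, n_new))
        hr, far = de.corrected_rates(hits, n_old, fas, n_new)
        assert 0.0 < hr < 1.0 and 0.0 < far < 1.0
        if hits < n_old:
            hr2, _ = de.corrected_rates(hits + 1, n_old, fas, n_new)
            assert hr2 > hr


class TestDprime:
    @pytest.mark.parametrize(
        "hr,far,expected,tol",
        [
            (0.5, 0.5, 0.0, 1e-12),
            (0.8413, 0.5, 1.0, 1e-3),
            (10.5 / 11, 0.5 / 11, 3.3812, 1e-3),
        ],
    )
    def test_inverse_normal_values(self, hr, far, expected, tol):
        assert de.dprime(hr, far) == pytest.approx(expected, abs=tol)

    def test_extreme_rates_raise(self):
        with pytest.raises(ValueError):
            de.dprime(1.0, 0.2)

    def test_equal_variance_observer_recovers_true_sensitivity(self):
        """d' from corrected rates of a d'=1.5 observer, 10^5 trials."""
        obs = syn.ObserverSpec(
            model="UVSD", dprime_link=(1.5, 0.0), vo=1.0, criteria=CRITERIA, seed=21
        )
        n = 10**5
        items = [syn.ItemSpec(f"o{i}", 0.5, "old") for i in range(n)] + [
            syn.ItemSpec(f"n{i}", 0.5, "new") for i in range(n)
        ]
        trials = syn.simulate_observer(obs, items, B=6)
        said_old = trials["response"] > 3
        hits = int((said_old & (trials["status"] == "old")).sum())
        fas = int((said_old & (trials["status"] == "new")).sum())
        hr, far = de.corrected_rates(hits, n, fas, n)
        assert de.dprime(hr, far) == pytest.approx(1.5, abs=0.05)


class TestBinMemorability:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.87, "high"), (0.45, "low"), (0.75, "mid"), (0.55, "low"), (0.76, "high")],
    )
    def test_bin_assignment(self, score, expected):
        assert de.bin_memorability(score) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            de.bin_memorability(1.2)


def _subject_trials(subject, n_correct, n_total, rng=None):
    """A subject with exactly n_correct correct old/new decisions."""
    n_old = n_total // 2
    rows = []
    for i in range(n_total):
        is_old = i < n_old
        rows.append(
            {
                "subject": subject,
                "image": f"im{i}",
                "status": "old" if is_old else "new",
                "memorability": 0.5,
                "response": 0,
                "statement": "none",
            }
        )
    df = pd.DataFrame(rows)
    correct_mask = np.zeros(n_total, dtype=bool)
    correct_mask[:n_correct] = True
    is_old = df["status"] == "old"
    df["response"] = np.where(correct_mask == is_old, 5, 2)
    return df


class TestExcludeAtChance:
    def test_exactly_chance_subject_is_excluded(self):
        kept, excluded = de.exclude_at_chance(_subject_trials("s1", 180, 360))
        assert excluded == ["s1"]

    def test_ceiling_subject_is_kept(self):
        kept, excluded = de.exclude_at_chance(_subject_trials("s1", 360, 360))
        assert kept == ["s1"]

    def test_weakly_above_chance_subject_is_kept(self):
        # 200/360 correct: exact binomial tail p ~ .02 < .05
        kept, excluded = de.exclude_at_chance(_subject_trials("s1", 200, 360))
        assert kept == ["s1"]


class TestROCConstruction:
    def test_perfect_observer_hits_one_at_zero_fa(self):
        counts = np.array([[0, 0, 0, 0, 0, 10], [10, 0, 0, 0, 0, 0]])
        pts = de.roc_points(counts)
        assert np.allclose(pts.hit, 1.0)
        assert np.allclose(pts.fa, 0.0)
        assert de.trapezoid_auc(pts) == pytest.approx(1.0)

    def test_identical_rows_fall_on_the_diagonal(self):
        counts = np.array([[3, 5, 2, 4, 1, 5], [3, 5, 2, 4, 1, 5]])
        pts = de.roc_points(counts)
        assert np.allclose(pts.hit, pts.fa)
        assert de.trapezoid_auc(pts) == pytest.approx(0.5)

    def test_points_match_closed_form_for_simulated_observer(self):
        from memroc import roc_models as rm

        params = rm.DPSDParams(0.3, 1.0, CRITERIA)
        probs = rm.dpsd_response_probs(params)
        rng = np.random.default_rng(6)
        counts = np.vstack(
            [rng.multinomial(10**5, probs[0]), rng.multinomial(10**5, probs[1])]
        )
        pts = de.roc_points(counts)
        pred_hit = np.cumsum(probs[0, ::-1])[:-1]
        pred_fa = np.cumsum(probs[1, ::-1])[:-1]
        assert np.abs(pts.hit - pred_hit).max() < 0.01
        assert np.abs(pts.fa - pred_fa).max() < 0.01

    def test_empty_row_raises(self):
        with pytest.raises(ValueError):
            de.roc_points(np.array([[0, 0, 0, 0, 0, 0], [1, 2, 3, 1, 1, 1]]))

    def test_z_transform_drops_divergent_endpoints(self):
        counts = np.array([[0, 0, 0, 0, 0, 10], [10, 0, 0, 0, 0, 0]])
        zf, zh = de.z_transform(de.roc_points(counts))
        assert len(zf) == 0  # all points at 0 or 1

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50)),
            min_size=2,
            max_size=8,
        ).filter(lambda c: sum(a for a, _ in c) > 0 and sum(b for _, b in c) > 0)
    )
    def test_cumulative_vectors_nondecreasing(self, counts):
        table = np.array(counts).T
        pts = de.roc_points(table)
        assert np.all(np.diff(pts.hit) >= -1e-12)
        assert np.all(np.diff(pts.fa) >= -1e-12)


class TestTrapezoidAUC:
    def test_single_interior_point_hand_geometry(self):
        pts = de.ROCPoints(fa=np.array([0.32]), hit=np.array([0.65]))
        # two trapezoids: 0.32*0.65/2 + 0.68*(0.65+1)/2
        assert de.trapezoid_auc(pts) == pytest.approx(0.665)

    def test_invariant_to_merging_collinear_points(self):
        a = de.ROCPoints(fa=np.array([0.2, 0.4]), hit=np.array([0.3, 0.5]))
        with_mid = de.ROCPoints(
            fa=np.array([0.2, 0.3, 0.4]), hit=np.array([0.3, 0.4, 0.5])
        )
        assert de.trapezoid_auc(a) == pytest.approx(de.trapezoid_auc(with_mid))


class TestImageLevelAssociation:
    def test_self_correlation_is_one(self, exp2_experiment):
        img = de.image_stats(exp2_experiment.head(5000))
        img["copy"] = img["memorability"]
        r, p = de.image_level_association(img, "copy")
        assert r == pytest.approx(1.0)

    def test_memorability_linked_sensitivity_is_recovered(self, exp2_experiment):
        img = de.image_stats(exp2_experiment)
        r, p = de.image_level_association(img, "dprime")
        assert r > 0.3 and p < 0.001

    def test_permuted_field_has_no_association(self, exp2_experiment):
        img = de.image_stats(exp2_experiment)
        rng = np.random.default_rng(0)
        img["shuffled"] = rng.permutation(img["dprime"].to_numpy())
        r, _ = de.image_level_association(img, "shuffled")
        assert abs(r) < 0.15

    def test_constant_vector_raises(self):
        table = pd.DataFrame({"memorability": [0.1, 0.2, 0.3], "x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            de.image_level_association(table, "x")


def test_plot_roc_writes_file(tmp_path, small_experiment):
    counts = de.rating_counts(small_experiment)
    pts = de.roc_points(counts)
    out = tmp_path / "roc.png"
    de.plot_roc(pts, str(out))
    assert out.exists() and out.stat().st_size > 0
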