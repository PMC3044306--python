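import numpy as np
import pytest
from scipy.stats import gumbel_l

from actsite.postprocess import (ConfigurationError, ScoredSite, fit_lr,
                                 fit_pints_null, lr_posterior,
                                 merge_rankings, pints_logF)
from actsite.synthetic import make_template
from oracles import irls_logistic


class TestLogisticRegression:
    def test_symmetric_data_has_half_posterior_at_zero(self):
        scores = np.array([1.0, 1.2, -1.0, -1.2])
        labels = np.array([1, 1, -1, -1])
        with pytest.warns(UserWarning):
            model = fit_lr(scores, labels)
        assert lr_posterior(model, 0.0) == pytest.approx(0.5, abs=1e-4)

    def test_four_point_fit_matches_irls_oracle(self):
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        labels = np.array([-1, -1, 1, 1])
        with pytest.warns(UserWarning, match="separated"):
            model = fit_lr(scores, labels)
        slope, intercept = irls_logistic(scores, labels, ridge=1e-6)
        assert model.slope == pytest.approx(slope, abs=1e-4)
        assert model.intercept == pytest.approx(intercept, abs=1e-4)

    def test_nonseparable_fit_matches_irls_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(60)
        labels = np.where(scores + rng.standard_normal(60) > 0, 1, -1)
        model = fit_lr(scores, labels)
        slope, intercept = irls_logistic(scores, labels, ridge=1e-6)
        assert model.slope == pytest.approx(slope, abs=1e-4)
        assert model.intercept == pytest.approx(intercept, abs=1e-4)

    def test_label_flip_negates_slope_and_complements_posterior(self):
        rng = np.random.default_rng(1)
        scores = rng.standard_normal(50)
        labels = np.where(scores + rng.standard_normal(50) > 0, 1, -1)
        model = fit_lr(scores, labels)
        flipped = fit_lr(scores, -labels)
        assert flipped.slope == pytest.approx(-model.slope, abs=1e-4)
        assert lr_posterior(flipped, 0.7) == pytest.approx(
            1 - lr_posterior(model, 0.7), abs=1e-4)

    def test_posterior_limits_and_center(self):
        model = fit_lr(np.array([2.0, 1.0, -1.0, -2.0, 0.5, -0.5]),
                       np.array([1, 1, -1, -1, -1, 1]))
        assert lr_posterior(model, 1e9) == pytest.approx(1.0)
        center = -model.intercept / model.slope
        assert lr_posterior(model, center) == pytest.approx(0.5, abs=1e-9)
        for s in (-5.0, 0.0, 5.0):
            assert 0.0 < lr_posterior(model, s) < 1.0

    def test_posterior_monotone_in_score(self):
        model = fit_lr(np.array([1.0, 2.0, -1.0, -2.0]),
                       np.array([1, 1, -1, -1]))
        grid = np.linspace(-3, 3, 50)
        values = [lr_posterior(model, s) for s in grid]
        assert np.all(np.diff(values) > 0)


class TestPints:
    @pytest.fixture
    def template(self):
        return make_template(4, seed=31)

    def test_fit_is_deterministic(self, template):
        devs = gumbel_l.rvs(loc=2.0, scale=0.4, size=200,
                            random_state=np.random.default_rng(5))
        a = fit_pints_null(devs, template)
        b = fit_pints_null(devs, template)
        assert (a.null_location, a.null_scale) == \
            (b.null_location, b.null_scale)
        assert a.matched_atom_count == template.m
        assert a.n_negatives == 200

    def test_expected_frequency_at_null_median(self, template):
        devs = gumbel_l.rvs(loc=2.0, scale=0.4, size=2000,
                            random_state=np.random.default_rng(6))
        model = fit_pints_null(devs, template)
        at_median = model.expected_frequency(float(np.median(devs)))
        assert at_median == pytest.approx(0.5 * 2000, rel=0.05)

    def test_expected_frequency_at_fifth_percentile(self, template):
        devs = gumbel_l.rvs(loc=1.5, scale=0.3, size=2000,
                            random_state=np.random.default_rng(7))
        model = fit_pints_null(devs, template)
        q05 = float(np.quantile(devs, 0.05))
        assert model.expected_frequency(q05) == pytest.approx(
            0.05 * 2000, rel=0.15)

    def test_location_equivariance_under_shift(self, template):
        devs = gumbel_l.rvs(loc=2.0, scale=0.4, size=300,
                            random_state=np.random.default_rng(8))
        a = fit_pints_null(devs, template)
        b = fit_pints_null(devs + 1.0, template)
        assert b.null_location == pytest.approx(a.null_location + 1.0,
                                                abs=1e-6)
        assert b.null_scale == pytest.approx(a.null_scale, abs=1e-6)

    def test_logF_strictly_increasing_in_deviation(self, template):
        devs = gumbel_l.rvs(loc=2.0, scale=0.4, size=100,
                            random_state=np.random.default_rng(9))
        model = fit_pints_null(devs, template)
        # strict over the null's support (up to its ~99.9th percentile)
        upper = model.null_location + 2 * model.null_scale
        grid = np.linspace(0.0, upper, 40)
        values = [pints_logF(model, d) for d in grid]
        assert np.all(np.diff(values) > 0)
        assert values[0] == min(values)  # deviation 0 is minimal

    def test_logF_decreasing_in_matched_atom_count(self):
        devs = gumbel_l.rvs(loc=2.0, scale=0.4, size=100,
                            random_state=np.random.default_rng(10))
        small = fit_pints_null(devs, make_template(4, seed=32))
        large = fit_pints_null(devs, make_template(8, seed=33))
        assert pints_logF(large, 1.0) < pints_logF(small, 1.0)

    def test_too_few_negatives_rejected(self, template):
        with pytest.raises(ValueError):
            fit_pints_null(np.ones(10), template)


def row(sid, res, tid, score, orientation, confidence=None):
    return ScoredSite(structure_id=sid, residue_label=res, template_id=tid,
                      score=score, orientation=orientation,
                      confidence=confidence)


class TestMergeRankings:
    def test_site_hit_by_two_templates_yields_two_rows(self):
        rows = [row("1abc", "ASP 137 A, ASP 194 A", "t1", 0.5, "deviation",
                    confidence=-14.0),
                row("1abc", "ASP 137 A, ASP 194 A", "t2", 0.6, "deviation",
                    confidence=-12.9)]
        table = merge_rankings(rows, "pints")
        assert len(table) == 2
        assert list(table["template_id"]) == ["t1", "t2"]
        assert list(table["rank"]) == [1, 2]

    def test_direct_similarity_sorts_descending(self):
        rows = [row("a", "r1", "t", 0.2, "similarity"),
                row("b", "r2", "t", 0.9, "similarity")]
        assert list(merge_rankings(rows, "direct")["structure_id"]) == \
            ["b", "a"]

    def test_direct_deviation_sorts_ascending(self):
        rows = [row("a", "r1", "t", 0.2, "deviation"),
                row("b", "r2", "t", 0.9, "deviation")]
        assert list(merge_rankings(rows, "direct")["structure_id"]) == \
            ["a", "b"]

    def test_equal_confidence_breaks_ties_deterministically(self):
        rows = [row(sid, res, "t", 1.0, "similarity")
                for sid, res in [("b", "x"), ("a", "y"), ("a", "x")]]
        table = merge_rankings(rows, "direct")
        assert list(zip(table["structure_id"], table["residues"])) == \
            [("a", "x"), ("a", "y"), ("b", "x")]

    def test_direct_mixing_orientations_is_an_error(self):
        rows = [row("a", "r1", "t1", 0.2, "deviation"),
                row("b", "r2", "t2", 0.9, "similarity")]
        with pytest.raises(ConfigurationError):
            merge_rankings(rows, "direct")

    def test_pints_on_similarity_rows_is_an_error(self):
        rows = [row("a", "r1", "t1", 0.2, "similarity", confidence=-3.0)]
        with pytest.raises(ConfigurationError):
            merge_rankings(rows, "pints")

    def test_lr_sorts_descending_by_posterior(self):
        rows = [row("a", "r1", "t1", 0.2, "deviation", confidence=0.3),
                row("b", "r2", "t2", 0.9, "deviation", confidence=0.8)]
        assert list(merge_rankings(rows, "lr")["structure_id"]) == ["b", "a"]
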