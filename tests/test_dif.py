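"""DIF screening: proportional-odds fits and the pseudo-R² criterion."""

import numpy as np
import pytest
from scipy.special import expit

from ghqcat import (
    PopulationSpec,
    dif_report,
    dif_statistic,
    draw_thetas,
    fit_cumulative_logit,
    sample_responses,
    screen_bank,
)


def simulate_po(n, beta, cutpoints, rng):
    """Draw from a proportional-odds model P(y<=k) = logistic(c_k - xβ)."""
    X = rng.normal(size=(n, len(beta)))
    eta = X @ np.asarray(beta)
    cum = expit(np.asarray(cutpoints)[None, :] - eta[:, None])
    u = rng.random(n)
    y = 1 + (u[:, None] > cum).sum(axis=1)
    return y, X


class TestCumulativeLogitFit:
    def test_intercept_only_closed_form(self, rng):
        y = rng.integers(1, 5, size=500)
        fit = fit_cumulative_logit(y)
        counts = np.bincount(y, minlength=5)[1:]
        cum = np.cumsum(counts)[:-1] / 500
        assert np.allclose(fit.intercepts, np.log(cum / (1 - cum)), atol=1e-10)
        expected_ll = np.sum(counts * np.log(counts / 500))
        assert fit.loglik == pytest.approx(expected_ll, abs=1e-10)

    def test_parameter_recovery(self, rng):
        beta = [0.8, -0.5]
        y, X = simulate_po(5000, beta, [-1.0, 0.5, 1.5], rng)
        fit = fit_cumulative_logit(y, X)
        assert fit.converged
        # within 3 SEs; SE of a logistic slope at n=5000 is well under 0.06
        assert np.allclose(fit.coefficients, beta, atol=0.18)
        assert np.all(np.diff(fit.intercepts) > 0)

    def test_loglik_matches_generic_optimizer(self, rng):
        """Independent oracle: statsmodels' ordered-logit MLE on a small
        fixture."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y, X = simulate_po(200, [0.6], [-0.5, 0.7], rng)
        ours = fit_cumulative_logit(y, X)
        sm_fit = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
        assert ours.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert ours.coefficients[0] == pytest.approx(
            sm_fit.params[0], abs=1e-3
        )

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_cumulative_logit(np.ones(50, dtype=int))


@pytest.fixture(scope="module")
def two_group_null(baseline_bank):
    thetas_a = draw_thetas(PopulationSpec(n=800, seed=51))
    thetas_b = draw_thetas(PopulationSpec(n=800, seed=52))
    resp_a = sample_responses(baseline_bank, thetas_a, seed=51)
    resp_b = sample_responses(baseline_bank, thetas_b, seed=52)
    return resp_a, resp_b


class TestDifStatistic:
    def test_group_constant_gives_zero(self, two_group_null):
        resp_a, _ = two_group_null
        y = resp_a.column(14)
        theta = np.zeros(resp_a.n)
        res = dif_statistic(y, y * 0.3, np.zeros(resp_a.n), item_id=14)
        assert res.pseudo_r2_change == 0.0
        assert not res.flagged

    def test_group_relabel_invariance(self, two_group_null, baseline_bank):
        resp_a, resp_b = two_group_null
        from ghqcat.estimation import eap_scores

        values = np.vstack([resp_a.values, resp_b.values])
        theta = eap_scores(values, baseline_bank)[0]
        y = values[:, baseline_bank.position(22)]
        g = np.concatenate([np.zeros(resp_a.n), np.ones(resp_b.n)])
        r1 = dif_statistic(y, theta, g, item_id=22)
        r2 = dif_statistic(y, theta, 1 - g, item_id=22)
        assert r1.pseudo_r2_change == pytest.approx(
            r2.pseudo_r2_change, abs=1e-8
        )
        assert 0.0 <= r1.pseudo_r2_change <= 1.0

    def test_nested_loglik_ordering(self, two_group_null, baseline_bank):
        resp_a, resp_b = two_group_null
        from ghqcat.estimation import eap_scores

        values = np.vstack([resp_a.values, resp_b.values])
        theta = eap_scores(values, baseline_bank)[0]
        g = np.concatenate([np.zeros(resp_a.n), np.ones(resp_b.n)])
        for item_id in (1, 16, 23):
            y = values[:, baseline_bank.position(item_id)]
            res = dif_statistic(y, theta, g, item_id=item_id)
            l0, l1, l2 = res.model_loglikelihoods
            assert l0 <= l1 + 1e-6 <= l2 + 2e-6

    def test_untestable_single_category(self):
        res = dif_statistic(np.ones(100, dtype=int), np.zeros(100),
                            np.repeat([0, 1], 50), item_id=3)
        assert res.untestable
        assert not res.flagged


class TestScreenBank:
    def test_identical_matrices_no_flags(self, two_group_null, baseline_bank):
        resp_a, _ = two_group_null
        results = screen_bank(resp_a, resp_a, baseline_bank)
        assert not any(r.flagged for r in results)

    def test_injected_dif_items_flagged(self, baseline_bank):
        """A clear uniform shift on three items flags exactly those items."""
        from ghqcat import inject_dif

        thetas_a = draw_thetas(PopulationSpec(n=2000, seed=61))
        thetas_b = draw_thetas(PopulationSpec(n=2000, seed=62))
        resp_a = sample_responses(baseline_bank, thetas_a, seed=61)
        bank_b = inject_dif(baseline_bank, [2, 14, 18], threshold_shift=1.5)
        resp_b = sample_responses(bank_b, thetas_b, seed=62)
        results = screen_bank(resp_a, resp_b, baseline_bank)
        flagged = sorted(r.item_id for r in results if r.flagged)
        assert flagged == [2, 14, 18]

    def test_followup_swap_orders_dif_items_first(self, baseline_bank,
                                                  followup_bank):
        """Group B responding under the follow-up parameters: item 16 (the
        largest printed parameter change) shows the largest pseudo-R²."""
        thetas_a = draw_thetas(PopulationSpec(n=2000, seed=61))
        thetas_b = draw_thetas(PopulationSpec(n=2000, seed=62))
        resp_a = sample_responses(baseline_bank, thetas_a, seed=61)
        resp_b = sample_responses(followup_bank, thetas_b, seed=62)
        results = screen_bank(resp_a, resp_b, baseline_bank)
        stats = {r.item_id: r.pseudo_r2_change for r in results}
        null_max = max(v for k, v in stats.items() if k not in (16, 19, 25))
        assert stats[16] == max(stats.values())
        assert stats[19] > null_max

    def test_unattainable_threshold(self, two_group_null, baseline_bank):
        resp_a, resp_b = two_group_null
        results = screen_bank(resp_a, resp_b, baseline_bank, threshold=1.0)
        assert not any(r.flagged for r in results)

    def test_monotone_in_effect_size(self, baseline_bank):
        """Median pseudo-R² change never decreases with the injected shift."""
        from ghqcat import inject_dif

        thetas_a = draw_thetas(PopulationSpec(n=1200, seed=63))
        thetas_b = draw_thetas(PopulationSpec(n=1200, seed=64))
        resp_a = sample_responses(baseline_bank, thetas_a, seed=63)
        medians = []
        for shift in (0.0, 0.25, 0.5, 1.0):
            bank_b = inject_dif(baseline_bank, [22], threshold_shift=shift)
            resp_b = sample_responses(bank_b, thetas_b, seed=64)
            results = screen_bank(resp_a, resp_b, baseline_bank)
            stat = [r.pseudo_r2_change for r in results if r.item_id == 22][0]
            medians.append(stat)
        assert all(b >= a - 1e-3 for a, b in zip(medians, medians[1:]))

    def test_purification_pass_runs(self, baseline_bank):
        from ghqcat import inject_dif

        thetas_a = draw_thetas(PopulationSpec(n=1500, seed=65))
        thetas_b = draw_thetas(PopulationSpec(n=1500, seed=66))
        resp_a = sample_responses(baseline_bank, thetas_a, seed=65)
        bank_b = inject_dif(baseline_bank, [2, 14, 18], threshold_shift=1.5)
        resp_b = sample_responses(bank_b, thetas_b, seed=66)
        plain = screen_bank(resp_a, resp_b, baseline_bank, purify=False)
        purified = screen_bank(resp_a, resp_b, baseline_bank, purify=True)
        assert {r.item_id for r in purified} == {r.item_id for r in plain}
        assert sorted(r.item_id for r in purified if r.flagged) == [2, 14, 18]

    def test_report_layout(self, two_group_null, baseline_bank):
        resp_a, resp_b = two_group_null
        df = dif_report(screen_bank(resp_a, resp_b, baseline_bank))
        assert list(df.columns) == [
            "item_id", "pseudo_r2_change", "flagged", "n_A", "n_B", "converged"
        ]
        assert len(df) == 30
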