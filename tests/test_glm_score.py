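"""Two-step GLM, junction posteriors, p-values, FDR, naive test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

from circjunct.classify import ReadFeatureRecord
from circjunct.glm import (
    GLMFit,
    bh_fdr,
    circular_junction_pvalue,
    fit_two_step_glm,
    junction_posterior,
    linear_junction_pvalue,
    log_odds_against,
    naive_mismatch_pvalue,
    null_moments,
    predict_conservative,
    report_calls,
    score_junctions,
)


def _feat(category, offset, score, mapq, rid="r", jid="j", mm=0, jcls=""):
    return ReadFeatureRecord(rid, jid, category, offset, score, mapq, mm, jcls)


def _draw_features(rng, n, category, offset_rng=(10, 51), score_mu=-3.0, mapq_mu=40.0):
    out = []
    for i in range(n):
        out.append(
            _feat(
                category,
                int(rng.integers(*offset_rng)),
                float(score_mu + rng.normal(0, 3)),
                float(np.clip(mapq_mu + rng.normal(0, 4), 0, 42)),
                rid=f"{category}{i}",
            )
        )
    return out


class TestTwoStepGLM:
    def test_identical_class_distributions_give_flat_probabilities(self):
        """With no class signal the model neither shifts nor discriminates:
        predicted probabilities hover at 0.5 and the AUC stays at chance."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            feats = _draw_features(rng, 500, "linear") + _draw_features(rng, 500, "decoy")
            fit = fit_two_step_glm(feats)
            assert abs(fit.p_hat.mean() - 0.5) < 0.05
            assert np.mean(np.abs(fit.p_hat - 0.5)) < 0.1
            lin = fit.p_hat[fit.labels == 1]
            dec = fit.p_hat[fit.labels == 2]
            auc = (lin[:, None] > dec[None, :]).mean() + 0.5 * (lin[:, None] == dec[None, :]).mean()
            assert abs(auc - 0.5) < 0.06

    def test_separated_classes_learn_direction(self):
        rng = np.random.default_rng(7)
        feats = _draw_features(rng, 500, "linear", mapq_mu=40) + _draw_features(
            rng, 500, "decoy", offset_rng=(10, 16), score_mu=-20, mapq_mu=10
        )
        fit = fit_two_step_glm(feats)
        lin_p = fit.p_hat[fit.labels == 1]
        dec_p = fit.p_hat[fit.labels == 2]
        assert lin_p.mean() > 0.9 and dec_p.mean() < 0.1

    def test_step2_downweights_conflicting_reads(self):
        rng = np.random.default_rng(7)
        feats = _draw_features(rng, 300, "linear", mapq_mu=40) + _draw_features(
            rng, 300, "decoy", offset_rng=(10, 16), score_mu=-20, mapq_mu=10
        )
        # one linear-labeled read whose features match the decoy profile
        conflicted = _feat("linear", 10, -24.0, 5.0, rid="conflicted")
        typical = _feat("linear", 40, 0.0, 42.0, rid="typical")
        feats = feats + [conflicted, typical]
        fit = fit_two_step_glm(feats)
        w = dict(zip([f.read_id for f in feats if f.category in ("linear", "decoy")], fit.weights))
        assert w["conflicted"] < w["typical"]

    def test_class_weight_totals_equal(self):
        rng = np.random.default_rng(3)
        feats = _draw_features(rng, 400, "linear") + _draw_features(rng, 150, "decoy", score_mu=-8)
        fit = fit_two_step_glm(feats)
        s1 = fit.weights[fit.labels == 1].sum()
        s2 = fit.weights[fit.labels == 2].sum()
        assert math.isclose(s1, s2, rel_tol=1e-12)

    def test_single_class_errors(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="per class"):
            fit_two_step_glm(_draw_features(rng, 50, "linear"))


class TestPredictConservative:
    def test_bound_choice_shrinks_toward_half(self):
        # hand-built fit: p-hat above 0.5 uses the lower bound, below the upper
        fit = GLMFit(
            beta=np.array([0.0, 0.1, 0.0, 0.0]), cov=np.eye(4) * 1e-4,
            p_hat=np.empty(0), ci_lo=np.empty(0), ci_hi=np.empty(0),
            weights=np.empty(0), labels=np.empty(0), coefficient_pvalues=np.empty(0),
        )
        high = _feat("circular", 30, 0, 0)   # eta = 3 -> p ~ 0.95
        low = _feat("circular", -30, 0, 0)   # eta = -3 -> p ~ 0.05
        p_hat, p_used = predict_conservative(fit, [high, low])
        _, lo, hi = fit.predict([high, low])
        assert p_used[0] == pytest.approx(lo[0]) and p_used[0] < p_hat[0]
        assert p_used[1] == pytest.approx(hi[1]) and p_used[1] > p_hat[1]

    def test_degenerate_interval_returns_point_estimate(self):
        fit = GLMFit(
            beta=np.array([0.0, 0.1, 0.0, 0.0]), cov=np.zeros((4, 4)),
            p_hat=np.empty(0), ci_lo=np.empty(0), ci_hi=np.empty(0),
            weights=np.empty(0), labels=np.empty(0), coefficient_pvalues=np.empty(0),
        )
        p_hat, p_used = predict_conservative(fit, [_feat("circular", 20, 0, 0)])
        assert p_used[0] == pytest.approx(p_hat[0])


class TestJunctionPosterior:
    def test_balanced_reads_give_half(self):
        for q in (0.1, 0.2, 0.35, 0.45):
            p_list = [q] * 4 + [1 - q] * 4
            assert junction_posterior(p_list) == pytest.approx(0.5, abs=1e-12)

    def test_uninformative_reads(self):
        assert junction_posterior([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_two_strong_reads(self):
        assert junction_posterior([0.9, 0.9]) == pytest.approx(0.81 / 0.82, rel=1e-12)

    def test_single_read_identity(self):
        assert junction_posterior([0.73]) == pytest.approx(0.73, abs=1e-9)

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=8),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_monotone(self, p_list, rnd):
        base = junction_posterior(p_list)
        shuffled = list(p_list)
        rnd.shuffle(shuffled)
        assert junction_posterior(shuffled) == pytest.approx(base, rel=1e-9)
        # adding a supportive read strictly increases the posterior
        assert junction_posterior(p_list + [0.8]) > base
        assert junction_posterior(p_list + [0.2]) < base


class TestLinearPvalue:
    def test_null_centered_reads_give_half(self):
        p = 0.3
        mu = float(log_odds_against([p])[0])
        assert linear_junction_pvalue([p] * 5, mu, 1.0) == pytest.approx(0.5)

    def test_supportive_junction_small_p(self):
        pool = np.linspace(0.2, 0.8, 200)
        mu, var1 = null_moments(pool)
        assert linear_junction_pvalue([0.85, 0.9, 0.8], mu, var1) < 0.5

    def test_nonpositive_variance_errors(self):
        with pytest.raises(ValueError):
            linear_junction_pvalue([0.5], 0.0, 0.0)


class TestCircularPvalue:
    def test_single_read(self):
        p, z = circular_junction_pvalue(1)
        assert z == pytest.approx(-2.0)
        assert p == pytest.approx(stats.norm.cdf(-2.0))

    def test_z_scales_with_sqrt_n(self):
        _, z4 = circular_junction_pvalue(4)
        assert z4 == pytest.approx(-4.0)

    def test_monotone_decreasing_in_n(self):
        ps = [circular_junction_pvalue(n)[0] for n in range(1, 10)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            circular_junction_pvalue(0)


def _bh_reference(pvals):
    """Textbook step-up BH, written independently."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestBHFDR:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_equal_spacing_collapses(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=1000)
        np.testing.assert_allclose(bh_fdr(p), _bh_reference(list(p)), atol=1e-12)

    def test_empty(self):
        assert bh_fdr([]).size == 0


class TestNaiveMismatchTest:
    def test_zero_mismatches_is_one(self):
        assert naive_mismatch_pvalue(0, 12345) == 1.0

    def test_known_value(self):
        # 5 mismatches over 100 bases at 1%: upper tail of Poisson(1)
        expect = 1 - stats.poisson.cdf(4, 1.0)
        assert naive_mismatch_pvalue(5, 100) == pytest.approx(expect, rel=1e-12)
        assert naive_mismatch_pvalue(5, 100) == pytest.approx(0.00366, abs=5e-6)

    def test_matches_pmf_summation_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            bases = int(rng.integers(50, 5000))
            k = int(rng.integers(0, 30))
            lam = 0.01 * bases
            oracle = 1.0 - sum(
                math.exp(-lam) * lam**i / math.factorial(i) for i in range(k)
            )
            assert naive_mismatch_pvalue(k, bases) == pytest.approx(oracle, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            naive_mismatch_pvalue(1, 0)
        with pytest.raises(ValueError):
            naive_mismatch_pvalue(-1, 100)


class TestReportCalls:
    def _calls(self):
        from circjunct.glm import JunctionCall

        return [
            JunctionCall("a", "scrambled", 3, 0.95, 0.01, 0.02),
            JunctionCall("b", "scrambled", 1, 0.95, 0.01, 0.02),
            JunctionCall("c", "scrambled", 10, 0.89, 0.01, 0.02),
        ]

    def test_threshold_filters(self):
        kept = report_calls(self._calls(), posterior_threshold=0.9, n_min=2)
        assert [c.junction_id for c in kept] == ["a"]

    def test_n_min_one_keeps_singletons(self):
        kept = report_calls(self._calls(), posterior_threshold=0.9, n_min=1)
        assert {c.junction_id for c in kept} == {"a", "b"}


def test_score_junctions_naive_mode_uses_mismatch_test():
    feats = [
        _feat("circular", 30, 0, 40, rid=f"r{i}", jid="good", mm=0) for i in range(4)
    ] + [
        _feat("circular", 12, -24, 5, rid=f"q{i}", jid="bad", mm=6) for i in range(4)
    ]
    calls = {c.junction_id: c for c in score_junctions(feats, mode="naive")}
    assert calls["good"].p_value == 1.0
    assert calls["bad"].p_value < 1e-6
    assert np.isnan(calls["good"].posterior)
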