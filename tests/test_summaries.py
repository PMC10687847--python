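"""Heritability algebra, genetic correlations, HPD intervals, posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import duelfit as dfit
from duelfit.summaries import (
    genetic_correlations,
    heritability_dominance,
    heritability_linear,
    hpd_interval,
    phenotypic_variance_dominance,
    posterior_summary,
)


def constrained_vc(v_a, v_pe, n=1):
    """Variance-component rows under the mirror constraint (no herd)."""
    return pd.DataFrame(
        {
            "sigma2_aD": [v_a] * n, "sigma2_aC": [v_a] * n, "sigma_aD_aC": [-v_a] * n,
            "sigma2_PeD": [v_pe] * n, "sigma2_PeC": [v_pe] * n,
            "sigma_PeD_PeC": [-v_pe] * n, "sigma2_e": [1.0] * n,
        }
    )


class TestPhenotypicVariance:
    @given(st.floats(min_value=1e-6, max_value=10.0),
           st.floats(min_value=0.0, max_value=10.0))
    @settings(deadline=None, max_examples=50)
    def test_constraint_collapses_to_residual(self, v_a, v_pe):
        vc = constrained_vc(v_a, v_pe)
        assert phenotypic_variance_dominance(vc)[0] == pytest.approx(1.0)

    def test_all_zero_but_residual(self):
        vc = constrained_vc(0.0, 0.0)
        assert phenotypic_variance_dominance(vc)[0] == 1.0

    def test_hand_sum(self):
        vc = pd.DataFrame(
            {"sigma2_aD": [0.15], "sigma2_aC": [0.15], "sigma_aD_aC": [-0.14],
             "sigma2_e": [1.0]}
        )
        assert phenotypic_variance_dominance(vc)[0] == pytest.approx(1.02)


class TestHeritability:
    @given(st.floats(min_value=1e-4, max_value=5.0),
           st.floats(min_value=0.0, max_value=5.0))
    @settings(deadline=None, max_examples=50)
    def test_constraint_gives_zero_total_and_exact_direct(self, v_a, v_pe):
        h = heritability_dominance(constrained_vc(v_a, v_pe))
        assert h["h2_total"][0] == pytest.approx(0.0, abs=1e-12)
        assert h["h2_direct"][0] == pytest.approx(v_a)  # sigma2_P = 1 exactly

    def test_constrained_reference_value(self):
        h = heritability_dominance(constrained_vc(0.1646, 0.05))
        assert h["h2_direct"][0] == pytest.approx(0.1646)

    def test_hand_computation(self):
        vc = pd.DataFrame(
            {"sigma2_aD": [0.2], "sigma2_aC": [0.2], "sigma_aD_aC": [0.0],
             "sigma2_PeD": [0.0], "sigma2_PeC": [0.0], "sigma_PeD_PeC": [0.0],
             "sigma2_e": [1.6]}
        )
        h = heritability_dominance(vc)
        assert h.iloc[0].to_list() == pytest.approx([0.1, 0.1, 0.2])

    def test_partition_inequality_matches_covariance_sign(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v1, v2 = rng.uniform(0.01, 1, 2)
            c = rng.uniform(-1, 1) * np.sqrt(v1 * v2)
            vc = pd.DataFrame(
                {"sigma2_aD": [v1], "sigma2_aC": [v2], "sigma_aD_aC": [c],
                 "sigma2_e": [1.0]}
            )
            h = heritability_dominance(vc).iloc[0]
            gap = h["h2_direct"] + h["h2_indirect"] - h["h2_total"]
            assert (gap >= -1e-12) == (c <= 1e-12)

    def test_linear_quarter(self):
        assert heritability_linear(
            {"sigma2_a": 1.0, "sigma2_pe": 1.0, "sigma2_e": 1.0, "sigma2_herd": 1.0}
        ) == pytest.approx(0.25)

    def test_linear_zero_genetic(self):
        assert heritability_linear({"sigma2_a": 0.0, "sigma2_e": 2.0}) == 0.0

    def test_linear_milk_magnitude(self):
        # components built so the ratio is 0.224 exactly
        assert heritability_linear(
            {"sigma2_a": 0.224, "sigma2_pe": 0.15, "sigma2_herd": 0.10,
             "sigma2_htd": 0.10, "sigma2_e": 0.426}
        ) == pytest.approx(0.224)

    def test_nonpositive_phenotypic_variance_raises(self):
        vc = constrained_vc(0.5, 0.1)
        vc["sigma2_e"] = 0.0
        with pytest.raises(ValueError):
            heritability_dominance(vc)


class TestGeneticCorrelations:
    def test_forced_minus_one(self):
        vc = pd.DataFrame(
            {"sigma2_a1": [1.0], "sigma2_aD2": [0.36], "sigma2_aC2": [0.36],
             "sigma_a1_aD2": [0.0], "sigma_a1_aC2": [0.0],
             "sigma_aD2_aC2": [-0.36]}
        )
        assert genetic_correlations(vc)["r_aD2_aC2"][0] == pytest.approx(-1.0)

    def test_zero_covariances(self):
        vc = pd.DataFrame(
            {"sigma2_a1": [1.0], "sigma2_aD2": [1.0], "sigma2_aC2": [1.0],
             "sigma_a1_aD2": [0.0], "sigma_a1_aC2": [0.0], "sigma_aD2_aC2": [0.0]}
        )
        assert (genetic_correlations(vc).iloc[0] == 0).all()

    def test_hand_value(self):
        vc = pd.DataFrame(
            {"sigma2_a1": [1.0], "sigma2_aD2": [0.36], "sigma2_aC2": [0.36],
             "sigma_a1_aD2": [0.3], "sigma_a1_aC2": [0.0], "sigma_aD2_aC2": [0.0]}
        )
        assert genetic_correlations(vc)["r_a1_aD2"][0] == pytest.approx(0.5)

    def test_zero_variance_is_undefined_not_zero(self):
        vc = pd.DataFrame(
            {"sigma2_a1": [0.0], "sigma2_aD2": [0.5], "sigma2_aC2": [0.5],
             "sigma_a1_aD2": [0.0], "sigma_a1_aC2": [0.0], "sigma_aD2_aC2": [0.1]}
        )
        out = genetic_correlations(vc)
        assert np.isnan(out["r_a1_aD2"][0])
        assert not np.isnan(out["r_aD2_aC2"][0])

    def test_bounded_by_one_under_psd(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            m = rng.standard_normal((3, 3))
            cov = m @ m.T
            vc = pd.DataFrame(
                {"sigma2_a1": [cov[0, 0]], "sigma2_aD2": [cov[1, 1]],
                 "sigma2_aC2": [cov[2, 2]], "sigma_a1_aD2": [cov[0, 1]],
                 "sigma_a1_aC2": [cov[0, 2]], "sigma_aD2_aC2": [cov[1, 2]]}
            )
            assert (genetic_correlations(vc).abs() <= 1 + 1e-10).all().all()


class TestHpdAndSummary:
    def exhaustive_hpd(self, x, prob=0.95):
        # scan every candidate interval of floor(prob*n)+1 sorted samples
        x = np.sort(x)
        n = len(x)
        m = int(np.floor(prob * n))
        best = (np.inf, None)
        for j in range(n - m):
            w = x[j + m] - x[j]
            if w < best[0]:
                best = (w, (x[j], x[j + m]))
        return best[1]

    def test_matches_exhaustive_scan_and_arviz(self):
        rng = np.random.default_rng(3)
        for x in (rng.standard_normal(5000), rng.gamma(2, 1, 3000),
                  rng.beta(0.5, 3, 800)):
            lo, hi = hpd_interval(x)
            elo, ehi = self.exhaustive_hpd(x)
            assert (lo, hi) == (pytest.approx(elo), pytest.approx(ehi))
            import arviz

            alo, ahi = arviz.hdi(x, hdi_prob=0.95)
            assert lo == pytest.approx(alo, abs=1e-8)
            assert hi == pytest.approx(ahi, abs=1e-8)

    def test_standard_normal_hpd(self):
        rng = np.random.default_rng(4)
        lo, hi = hpd_interval(rng.standard_normal(200_000))
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_constant_chain(self):
        s = posterior_summary(np.full(500, 3.3), "const")
        assert s.posterior_mean == pytest.approx(3.3)
        assert s.hpd95_low == s.hpd95_high == 3.3
        assert s.posterior_se == pytest.approx(0.0, abs=1e-12)
        assert s.significant

    def test_all_positive_significant(self):
        rng = np.random.default_rng(5)
        s = posterior_summary(rng.uniform(0.1, 0.2, 1000), "v")
        assert s.significant

    def test_zero_covered_not_significant(self):
        rng = np.random.default_rng(6)
        s = posterior_summary(rng.standard_normal(1000), "v")
        assert not s.significant

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least"):
            posterior_summary(np.arange(10.0))

    def test_undefined_samples_counted(self):
        x = np.concatenate([np.full(50, np.nan), np.random.default_rng(7).random(500)])
        s = posterior_summary(x, "r")
        assert s.n_undefined == 50
        assert s.n_samples == 500


class TestPerSampleOrdering:
    def test_summaries_are_per_sample_then_aggregated(self):
        """On a skewed chain, the mean of per-sample ratios differs from the
        ratio of means; the implementation must follow the per-sample order."""
        rng = np.random.default_rng(8)
        n = 4000
        v = rng.gamma(1.2, 0.3, n)
        vc = pd.DataFrame(
            {"sigma2_aD": v, "sigma2_aC": v * rng.gamma(4, 0.25, n),
             "sigma_aD_aC": -0.5 * v, "sigma2_PeD": rng.gamma(2, 0.1, n),
             "sigma2_PeC": rng.gamma(2, 0.1, n), "sigma_PeD_PeC": np.zeros(n),
             "sigma2_e": np.ones(n)}
        )
        h = heritability_dominance(vc)
        per_sample_mean = h["h2_direct"].mean()
        ratio_of_means = (
            vc["sigma2_aD"].mean()
            / phenotypic_variance_dominance(vc.mean().to_dict())
        )
        assert abs(per_sample_mean - ratio_of_means) > 1e-3  # orders distinguishable
        assert per_sample_mean == pytest.approx(
            np.mean(vc["sigma2_aD"] / phenotypic_variance_dominance(vc))
        )
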