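"""GEE association: sandwich variance, marker tests, conditional selection."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

import util
from admixfine.assoc import (
    confounding_ratio,
    forward_select,
    gee_logistic,
    la_association,
    ld_r2,
    snp_association,
    stratified_or_by_ancestry,
)
from admixfine.cohort import AncestralFrequencies
from admixfine.simcohort import DiseaseModel, SimConfig, simulate_cohort


class TestGeeLogistic:
    def test_singleton_clusters_reproduce_logistic_mle(self, rng):
        n = 300
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=n),
                          "z": rng.binomial(2, 0.3, n).astype(float)})
        y = rng.binomial(1, expit(-0.3 + 0.5 * X["x"] - 0.2 * X["z"]))
        fit = gee_logistic(y, X, np.arange(n))
        mle = sm.Logit(y, X).fit(disp=0)
        assert np.abs(fit.params - mle.params).max() < 1e-6
        robust = sm.Logit(y, X).fit(disp=0, cov_type="HC0")
        assert np.allclose(fit.robust_se, robust.bse, rtol=5e-3)

    def test_two_by_two_slope_is_log_odds_ratio(self):
        # counts: exposed cases a=30, exposed controls b=20,
        #         unexposed cases c=25, unexposed controls d=60
        a, b, c, d = 30, 20, 25, 60
        g = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        X = pd.DataFrame({"const": 1.0, "genotype": g})
        fit = gee_logistic(y, X, np.arange(len(y)))
        assert fit.params["genotype"] == pytest.approx(np.log(a * d / (b * c)),
                                                       abs=1e-6)

    def test_sandwich_matches_hand_computation(self):
        """Six individuals in three clusters: the cluster-robust covariance
        equals bread^-1 meat bread^-1 computed explicitly."""
        X = np.column_stack([np.ones(6), [0, 0, 1, 1, 2, 2]]).astype(float)
        y = np.array([0, 1, 0, 1, 1, 1.0])
        clusters = np.array([0, 0, 1, 1, 2, 2])
        fit = gee_logistic(y, pd.DataFrame(X, columns=["const", "g"]), clusters)
        eta = X @ fit.params.to_numpy()
        mu = expit(eta)
        hand = util.sandwich_by_hand(X, y, mu, clusters)
        assert np.allclose(fit.cov.to_numpy(), hand, rtol=1e-5, atol=1e-8)

    def test_rank_deficiency_rejected(self, rng):
        X = pd.DataFrame({"const": 1.0, "a": rng.normal(size=50)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="rank"):
            gee_logistic(rng.binomial(1, 0.5, 50), X, np.arange(50))

    def test_perfect_separation_rejected(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        X = pd.DataFrame({"const": 1.0, "sep": x})
        with pytest.raises(ValueError, match="separation"):
            gee_logistic(y, X, np.arange(40))


def _cohort_with_effect(log_or, n=3000, seed=21, f=(0.35, 0.35), gamma=0.0):
    cfg = SimConfig(
        n_individuals=n, n_families=0, n_markers=2, seed=seed,
        freq_table=AncestralFrequencies(np.full(2, f[0]), np.full(2, f[1])),
        disease=DiseaseModel(intercept=logit(0.4), causal={0: log_or}, gamma=gamma))
    return simulate_cohort(cfg)


class TestSnpAssociation:
    def test_effect_recovery(self):
        c = _cohort_with_effect(np.log(2))
        res = snp_association(c, 0)
        assert abs(res.beta - np.log(2)) < 2 * res.se
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert res.p_value < 1e-4

    def test_null_marker_covers_one(self):
        c = _cohort_with_effect(np.log(2))
        res = snp_association(c, 1)  # second marker has no effect
        assert res.p_value > 1e-3 or (res.ci_low < 1 < res.ci_high)

    def test_monomorphic_rejected(self):
        cfg = SimConfig(n_individuals=50, n_families=0, n_markers=1, seed=3,
                        freq_table=AncestralFrequencies.constant(1, 1.0, 1.0))
        with pytest.raises(ValueError, match="monomorphic"):
            snp_association(simulate_cohort(cfg), 0)

    def test_minor_allele_coding(self):
        """The coded allele is the cohort minor allele, so f_case/f_control
        are below one half on average."""
        c = _cohort_with_effect(0.0, f=(0.8, 0.9), n=800)
        res = snp_association(c, 0)
        assert res.coded_allele == str(c.markers["ref"][0])
        assert res.f_control < 0.5

    def test_missing_dropped_per_marker(self):
        c = _cohort_with_effect(0.0, n=500)
        c.genotypes[:100, 0] = np.nan
        res = snp_association(c, 0)
        assert res.n_individuals == 400


class TestConfounding:
    def test_equal_betas_zero(self):
        assert confounding_ratio(0.7, 0.7) == 0.0

    def test_worked_arithmetic(self):
        got = confounding_ratio(np.log(1.5), np.log(3.0))
        assert got == pytest.approx(abs(np.log(1.5) - np.log(3)) / np.log(3))
        assert got == pytest.approx(0.6309, abs=1e-4)

    def test_zero_unadjusted_rejected(self):
        with pytest.raises(ValueError):
            confounding_ratio(0.1, 0.0)


class TestStratifiedOr:
    def test_homogeneous_effect_across_strata(self):
        c = _cohort_with_effect(np.log(2), n=6000, f=(0.4, 0.4))
        out = stratified_or_by_ancestry(c, 0)
        betas = {a: r.beta for a, r in out.items() if r is not None}
        ses = {a: r.se for a, r in out.items() if r is not None}
        assert len(betas) >= 2
        keys = list(betas)
        for i in range(len(keys) - 1):
            a, b = keys[i], keys[i + 1]
            pooled = np.hypot(ses[a], ses[b])
            assert abs(betas[a] - betas[b]) < 3 * pooled

    def test_empty_stratum_reported_unavailable(self):
        cfg = SimConfig(n_individuals=300, n_families=0, n_markers=1, seed=5,
                        theta_mean=0.98, theta_sd=0.01,
                        freq_table=AncestralFrequencies.constant(1, 0.5, 0.5))
        c = simulate_cohort(cfg)
        out = stratified_or_by_ancestry(c, 0)
        assert out[0] is None  # essentially no European-homozygous stratum


class TestLaAssociation:
    def test_conditioning_on_causal_kills_ancestry_signal(self):
        """When one SNP with an ancestral frequency differential drives the
        ancestry association, conditioning on it removes the signal."""
        cfg = SimConfig(
            n_individuals=4000, n_families=0, n_markers=1, seed=9,
            freq_table=AncestralFrequencies.constant(1, 0.09, 0.65),
            disease=DiseaseModel(intercept=logit(0.3), causal={0: np.log(1.8)}))
        c = simulate_cohort(cfg)
        raw = la_association(c, 0)
        cond = la_association(c, 0, conditioning_markers=[0])
        assert raw.p_value < cond.p_value
        assert cond.p_value > 0.01

    def test_zero_variance_ancestry_rejected(self):
        cfg = SimConfig(n_individuals=100, n_families=0, n_markers=1, seed=10,
                        theta_mean=0.999, theta_sd=0.0005)
        c = simulate_cohort(cfg)
        c.local_ancestry[:] = 2
        with pytest.raises(ValueError, match="variance"):
            la_association(c, 0)


class TestForwardSelect:
    def _two_causal_cohort(self, seed=31):
        cfg = SimConfig(
            n_individuals=4000, n_families=0, n_markers=4, seed=seed,
            freq_table=AncestralFrequencies.constant(4, 0.4, 0.4),
            disease=DiseaseModel(intercept=logit(0.35),
                                 causal={0: np.log(2.2), 2: np.log(1.6)}))
        return simulate_cohort(cfg)

    def test_two_independent_causals_selected_in_order(self):
        c = self._two_causal_cohort()
        sel = forward_select(c, list(range(4)), alpha=0.01)
        ids = [m for m, _ in sel]
        assert ids[:2] == ["rs000000", "rs000002"]

    def test_no_signal_empty_selection(self):
        cfg = SimConfig(n_individuals=500, n_families=0, n_markers=3, seed=32,
                        freq_table=AncestralFrequencies.constant(3, 0.4, 0.4))
        c = simulate_cohort(cfg)
        assert forward_select(c, [0, 1, 2], alpha=1e-4) == []

    def test_duplicated_marker_never_selected_twice(self):
        c = self._two_causal_cohort()
        c.genotypes[:, 1] = c.genotypes[:, 0]  # perfect copy of the top SNP
        sel = forward_select(c, list(range(4)), alpha=0.01)
        ids = [m for m, _ in sel]
        assert "rs000001" not in ids and "rs000000" in ids


class TestLdR2:
    def test_identical_vectors(self, rng):
        g = rng.binomial(2, 0.3, 250).astype(float)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_allele_relabeling(self, rng):
        g = rng.binomial(2, 0.3, 250).astype(float)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_markers_near_zero(self, rng):
        below = sum(ld_r2(rng.binomial(2, 0.3, 250).astype(float),
                          rng.binomial(2, 0.4, 250).astype(float)) < 0.05
                    for _ in range(100))
        assert below >= 95

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            ld_r2(np.ones(50), rng.binomial(2, 0.5, 50).astype(float))
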