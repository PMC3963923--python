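"""ADM / SNP1 / MIX / DIFF scores: exact cases, recovery, identities, regions."""
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2

from admixfine import admixscore as ax
from admixfine.cohort import AncestralFrequencies
from admixfine.simcohort import (
    DiseaseModel,
    SimConfig,
    simulate_cohort,
    simulate_marker_scenario,
)


class TestAncestralFreqEstimation:
    def test_single_background_error(self):
        with pytest.raises(ValueError, match="background"):
            ax.estimate_ancestral_freqs([1, 2, 0], [2, 2, 2])

    def test_phase_unambiguous_closed_form(self):
        # ancestry-homozygous individuals only: stratified counts
        g = np.array([2, 1, 0, 0, 1, 2])
        a = np.array([2, 2, 2, 0, 0, 0])
        pa, pe = ax.estimate_ancestral_freqs(g, a)
        assert pa == pytest.approx(3 / 6)
        assert pe == pytest.approx(3 / 6)

    def test_em_matches_direct_maximization(self, rng):
        """EM fixed point agrees with direct numeric ML on data containing
        ancestry heterozygotes."""
        g, a, th, y = simulate_marker_scenario(0, 800, 0.3, 0.7, rng)
        pa, pe = ax.estimate_ancestral_freqs(g, a, y, controls_only=False)
        lik = ax._Snp1Likelihood(g, a, y)
        res = minimize(
            lambda q: -lik.loglik(1.0, 1 / (1 + np.exp(-q[0])), 1 / (1 + np.exp(-q[1]))),
            [0.0, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12})
        pa_d = 1 / (1 + np.exp(-res.x[0]))
        pe_d = 1 / (1 + np.exp(-res.x[1]))
        assert pa == pytest.approx(pa_d, abs=1e-6)
        assert pe == pytest.approx(pe_d, abs=1e-6)

    def test_recovery(self, rng):
        g, a, th, y = simulate_marker_scenario(0, 5000, 0.42, 0.51, rng)
        pa, pe = ax.estimate_ancestral_freqs(g, a, y, controls_only=False)
        n_hap_a = a.sum()
        assert abs(pa - 0.42) < 3 * np.sqrt(0.42 * 0.58 / n_hap_a)
        assert abs(pe - 0.51) < 3 * np.sqrt(0.51 * 0.49 / (2 * len(a) - n_hap_a))


class TestAdmScore:
    def test_exact_null_configuration(self):
        """theta = 1/2 and every case ancestry-heterozygous: lambda_hat = 1."""
        a = np.ones(50)
        th = np.full(50, 0.5)
        stat, p, lam = ax.adm_score(a, th)
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)
        assert lam == pytest.approx(1.0, abs=1e-4)

    def test_lambda_recovery(self, rng):
        lam_true = 1.3
        lams = []
        for _ in range(40):
            g, a, th, y = simulate_marker_scenario(
                1000, 0, 0.5, 0.5, rng, ancestry_or=lam_true)
            lams.append(ax.adm_score(a, th)[2])
        lams = np.array(lams)
        se = lams.std(ddof=1) / np.sqrt(lams.size)
        assert abs(lams.mean() - lam_true) < 2 * se

    def test_boundary_theta_skipped(self):
        a = np.array([2, 1, 0, 1])
        th = np.array([1.0, 0.5, 0.0, 0.5])
        stat, p, lam = ax.adm_score(a, th)  # only the two theta=0.5 cases count
        assert np.isfinite(stat)
        with pytest.raises(ValueError, match="informative"):
            ax.adm_score([2, 0], [1.0, 0.0])


class TestSnp1Score:
    def test_plugin_collapses_to_allelic_lrt_when_freqs_equal(self, rng):
        """With p_A = p_E supplied, the likelihood depends only on total
        allele counts, so SNP1 equals the binomial allelic LRT."""
        p0 = 0.4
        g, a, th, y = simulate_marker_scenario(400, 400, p0, p0, rng,
                                               allelic_or=1.3)
        stat, p, r = ax.snp1_score(g, a, y, p0, p0)
        # oracle: binomial LRT on allele counts, control freq fixed at p0
        k1, n1 = g[y == 1].sum(), 2 * (y == 1).sum()

        def ll(q):
            return k1 * np.log(q) + (n1 - k1) * np.log1p(-q)

        q_hat = k1 / n1
        oracle = 2 * (ll(q_hat) - ll(p0))
        assert stat == pytest.approx(oracle, abs=1e-6)

    def test_r_recovery(self, rng):
        rs = []
        for _ in range(30):
            g, a, th, y = simulate_marker_scenario(800, 800, 0.3, 0.5, rng,
                                                   allelic_or=2.0)
            rs.append(ax.snp1_score(g, a, y)[2])
        rs = np.array(rs)
        se = rs.std(ddof=1) / np.sqrt(rs.size)
        assert abs(rs.mean() - 2.0) < 2.5 * se

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ax.snp1_score([2, 2, 2], [1, 1, 2], [0, 1, 0])

    def test_degenerate_plugin_freqs_rejected(self, rng):
        g, a, th, y = simulate_marker_scenario(50, 50, 0.5, 0.5, rng)
        with pytest.raises(ValueError, match="degenerate"):
            ax.snp1_score(g, a, y, 0.0, 1.0)


class TestMixScore:
    def test_constraint_collapse_when_freqs_equal(self, rng):
        """p_A = p_E makes lambda(r) = 1: MIX reduces to SNP1 and DIFF to ADM."""
        p0 = 0.45
        g, a, th, y = simulate_marker_scenario(500, 500, p0, p0, rng,
                                               allelic_or=1.4)
        s_snp = ax.snp1_score(g, a, y, p0, p0)
        s_mix = ax.mix_score(g, a, th, y, p0, p0)
        s_adm = ax.adm_score(a[y == 1], th[y == 1])
        assert s_mix[0] == pytest.approx(s_snp[0], abs=1e-6)
        diff = s_adm[0] + s_snp[0] - s_mix[0]
        assert diff == pytest.approx(s_adm[0], abs=1e-6)

    def test_constrained_argmax_matches_dense_grid(self, rng):
        """Plug-in mode: optimizer argmax over r equals a dense grid search."""
        g, a, th, y = simulate_marker_scenario(400, 400, 0.2, 0.6, rng,
                                               allelic_or=1.5)
        pa, pe = ax.estimate_ancestral_freqs(g, a, y)
        _, _, r_opt = ax.mix_score(g, a, th, y, pa, pe)
        adm_lik = ax._AdmLikelihood(a[y == 1], th[y == 1])
        snp_lik = ax._Snp1Likelihood(g, a, y)
        grid = np.exp(np.linspace(np.log(1 / 50), np.log(50), 20001))
        vals = [adm_lik.loglik(ax.induced_ancestry_or(r, pa, pe))
                + snp_lik.loglik(r, pa, pe) for r in grid]
        r_grid = grid[int(np.argmax(vals))]
        assert abs(np.log(r_opt) - np.log(r_grid)) < 1e-3

    def test_pure_ancestry_effect_yields_large_diff(self, rng):
        """Data with an ancestry effect but no allelic effect: the single-
        causal constraint fails, so DIFF carries the signal."""
        diffs, mixes = [], []
        for _ in range(20):
            g, a, th, y = simulate_marker_scenario(600, 600, 0.4, 0.45, rng,
                                                   ancestry_or=1.5)
            s = ax.admixture_scores(g, a, th, y)
            diffs.append(s.diff_stat)
            mixes.append(s.mix_stat)
        assert np.median(diffs) > np.median(mixes)


class TestDiffScore:
    def test_identity_and_exact_explanation(self):
        stat, p = ax.diff_score(3.0, 4.0, 7.0)
        assert stat == 0.0 and p == 1.0

    def test_negative_beyond_tolerance_rejected(self):
        with pytest.raises(ValueError):
            ax.diff_score(1.0, 1.0, 3.0)

    def test_accepts_score_set(self, rng):
        g, a, th, y = simulate_marker_scenario(300, 300, 0.3, 0.6, rng)
        s = ax.admixture_scores(g, a, th, y)
        stat, p = ax.diff_score(s)
        assert stat == pytest.approx(s.diff_stat, abs=1e-12)

    def test_identity_holds_across_random_markers(self, rng):
        for _ in range(15):
            pa, pe = rng.uniform(0.1, 0.9, 2)
            r = float(np.exp(rng.normal(0, 0.3)))
            g, a, th, y = simulate_marker_scenario(300, 300, pa, pe, rng,
                                                   allelic_or=r)
            s = ax.admixture_scores(g, a, th, y)
            assert s.diff_stat == pytest.approx(
                s.adm_stat + s.snp1_stat - s.mix_stat, abs=1e-8)
            assert s.mix_stat <= s.adm_stat + s.snp1_stat + 1e-8
            assert min(s.adm_stat, s.snp1_stat, s.mix_stat, s.diff_stat) >= 0


@pytest.fixture(scope="module")
def family_cohort():
    cfg = SimConfig(n_individuals=260, n_families=30, sibship_size=2,
                    n_markers=8, seed=17,
                    freq_table=AncestralFrequencies.random(
                        8, np.random.default_rng(5), 0.2, 0.8))
    return simulate_cohort(cfg)


class TestAveragedMix:
    def test_single_sample_equals_direct_call(self, family_cohort):
        rng1 = np.random.default_rng(3)
        s1 = ax.averaged_mix(family_cohort, 0, n_samples=1,
                             subsample_sizes=(60, 60), rng=rng1)
        # replay the same draw
        from admixfine import kin
        rel = kin.pedigree_relationship(
            kin.Pedigree.from_samples(family_cohort.samples))
        pool = set(kin.unrelated_subset(rel))
        ids = family_cohort.samples["id"].astype(str)
        in_pool = ids.isin(pool).to_numpy()
        rng2 = np.random.default_rng(3)
        case_rows = np.flatnonzero(in_pool & (family_cohort.status == 1))
        ctrl_rows = np.flatnonzero(in_pool & (family_cohort.status == 0))
        rows = np.concatenate([rng2.choice(case_rows, 60, replace=False),
                               rng2.choice(ctrl_rows, 60, replace=False)])
        s2 = ax.admixture_scores(
            family_cohort.genotypes[rows, 0], family_cohort.local_ancestry[rows, 0],
            family_cohort.theta[rows], family_cohort.status[rows])
        assert s1.mix_stat == pytest.approx(s2.mix_stat, abs=1e-10)
        assert s1.adm_stat == pytest.approx(s2.adm_stat, abs=1e-10)

    def test_deterministic_under_seed(self, family_cohort):
        a = ax.averaged_mix(family_cohort, 1, n_samples=3,
                            subsample_sizes=(60, 60),
                            rng=np.random.default_rng(11))
        b = ax.averaged_mix(family_cohort, 1, n_samples=3,
                            subsample_sizes=(60, 60),
                            rng=np.random.default_rng(11))
        assert a == b

    def test_insufficient_pool_rejected(self, family_cohort):
        with pytest.raises(ValueError, match="pool"):
            ax.averaged_mix(family_cohort, 0, n_samples=1,
                            subsample_sizes=(933, 846),
                            rng=np.random.default_rng(0))


class TestRegionsAndScreen:
    def test_region_boundaries_examples(self):
        pos = np.array([10, 20, 30, 40, 50])
        assert ax.region_boundaries(pos, [0.2, 0.01, 0.3, 0.04, 0.9]) == (20, 40)
        assert ax.region_boundaries(pos, [0.01] * 5) == (10, 50)
        assert ax.region_boundaries(pos, [0.5] * 5) is None
        with pytest.raises(ValueError):
            ax.region_boundaries(pos, [0.5] * 4)

    def test_tiered_screen(self):
        p = {"a": 0.2, "b": 0.01, "c": 0.01, "d": 0.03}
        cr = {"a": 0.01, "b": 0.5, "c": 0.02, "d": None}
        assert ax.tiered_screen(p, cr) == ["c"]

    def test_tier_labels(self, rng):
        g, a, th, y = simulate_marker_scenario(200, 200, 0.3, 0.6, rng)
        s = ax.admixture_scores(g, a, th, y)
        assert s.tier() in ("", "suggestive", "genome-wide")
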