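"""Admixture-signal score statistics: ADM, SNP1, MIX and DIFF.

The question these statistics answer: does a single candidate SNP explain an
observed excess of one ancestry among cases?  All four are 1-df likelihood
ratio tests built from two pieces of a retrospective likelihood:

* ADM (affected-only admixture score).  Among cases, the diploid
  African-allele count at a locus is Binomial(2, lam*theta / (lam*theta + 1
  - theta)) where theta is the individual's global African ancestry and lam
  is the ancestry odds ratio at the locus; ADM tests lam = 1.

* SNP1 (allelic score conditional on local ancestry).  Haplotypes of
  African / European origin carry the coded allele with frequency p_A / p_E
  in controls; in cases the frequency is inflated to p*r / (1 + (r-1)*p)
  under an allelic odds ratio r (rare-disease retrospective likelihood).
  Ancestry-heterozygous individuals are unphased, so their genotype
  probability sums over the two origin assignments.  SNP1 tests r = 1.

* MIX.  Under the hypothesis that this one SNP is the sole cause of the
  ancestry signal, the ancestry odds ratio is not free but induced by the
  allelic effect and the ancestral frequency differential:
  lam(r) = (1 + (r-1) p_A) / (1 + (r-1) p_E).  MIX maximizes the joint
  likelihood ADM + SNP1 along this one-dimensional curve; a small MIX p at
  a SNP marks it as able to account for the admixture peak.

* DIFF = ADM + SNP1 - MIX, the likelihood-ratio test of the single-causal
  constraint itself (2 free parameters vs 1): DIFF p < 0.05 indicates the
  ancestry signal needs more than this SNP.  The identity holds exactly
  because the three statistics share one likelihood.

All p-values are upper-tail 1-df chi-square.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .cohort import AdmixedCohort
from . import kin

_LOG_R_LO, _LOG_R_HI = np.log(1 / 50), np.log(50.0)
_TINY = 1e-300


@dataclass
class AdmixtureScoreSet:
    """ADM / SNP1 / MIX / DIFF statistics and p-values for one marker."""

    marker_id: str
    adm_stat: float
    adm_p: float
    snp1_stat: float
    snp1_p: float
    mix_stat: float
    mix_p: float
    diff_stat: float
    diff_p: float
    lam_hat: float      #: unconstrained ancestry odds ratio (ADM MLE)
    r_hat: float        #: unconstrained allelic odds ratio (SNP1 MLE)
    r_mix: float        #: allelic odds ratio under the single-causal constraint
    p_afr: float
    p_eur: float
    n_cases: int = 0
    n_controls: int = 0

    def tier(self) -> str:
        """Significance label for the MIX p-value (reporting only)."""
        if self.mix_p < 5e-8:
            return "genome-wide"
        if self.mix_p < 1e-5:
            return "suggestive"
        return ""


# ---------------------------------------------------------------------------
# ancestral allele frequencies
# ---------------------------------------------------------------------------

def estimate_ancestral_freqs(genotypes, local_ancestry, status=None,
                             controls_only: bool = True, tol: float = 1e-12,
                             max_iter: int = 1000) -> tuple[float, float]:
    """ML frequencies of the coded allele on African / European haplotypes.

    Ancestry-homozygous individuals contribute closed-form counts; for
    ancestry heterozygotes the origin of each allele copy is latent and the
    likelihood is maximized by EM.  With no ancestry heterozygotes the EM
    fixed point is the stratified count estimate.
    """
    g = np.asarray(genotypes, dtype=float)
    a = np.asarray(local_ancestry)
    if status is not None and controls_only:
        mask = np.asarray(status) == 0
        g, a = g[mask], a[mask]
    keep = ~np.isnan(g)
    g, a = g[keep], a[keep]
    n_afr_hap = float(np.sum(a))
    n_eur_hap = float(np.sum(2 - a))
    if n_afr_hap == 0 or n_eur_hap == 0:
        raise ValueError("both ancestral backgrounds must be represented")

    afr_hom = a == 2
    eur_hom = a == 0
    het = a == 1
    k_afr_fixed = float(g[afr_hom].sum())
    k_eur_fixed = float(g[eur_hom].sum())
    het_g1 = int(np.sum(g[het] == 1))
    het_g2 = int(np.sum(g[het] == 2))

    p_a = (k_afr_fixed + 0.5 * (het_g1 + 2 * het_g2)) / max(n_afr_hap, 1.0)
    p_e = (k_eur_fixed + 0.5 * (het_g1 + 2 * het_g2)) / max(n_eur_hap, 1.0)
    p_a, p_e = float(np.clip(p_a, 1e-9, 1 - 1e-9)), float(np.clip(p_e, 1e-9, 1 - 1e-9))
    if het_g1 == 0:  # no latent assignments: closed form, no EM needed
        p_a = (k_afr_fixed + het_g2) / n_afr_hap
        p_e = (k_eur_fixed + het_g2) / n_eur_hap
        return float(p_a), float(p_e)

    for _ in range(max_iter):
        # E-step: P(the single copy sits on the African-origin haplotype)
        w = p_a * (1 - p_e) / max(p_a * (1 - p_e) + p_e * (1 - p_a), _TINY)
        new_a = (k_afr_fixed + het_g2 + w * het_g1) / n_afr_hap
        new_e = (k_eur_fixed + het_g2 + (1 - w) * het_g1) / n_eur_hap
        if abs(new_a - p_a) < tol and abs(new_e - p_e) < tol:
            p_a, p_e = new_a, new_e
            break
        p_a, p_e = new_a, new_e
    return float(p_a), float(p_e)


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def _maximize_scalar(neg_fun, lo: float = _LOG_R_LO, hi: float = _LOG_R_HI,
                     n_grid: int = 33) -> tuple[float, float]:
    """Grid-bracketed scalar maximization; returns (argmax, max value).

    A coarse grid locates the basin, then Brent refines within the
    bracketing neighbours; robust to plateaus near boundary frequencies.
    """
    xs = np.linspace(lo, hi, n_grid)
    vals = np.array([neg_fun(x) for x in xs])
    if not np.all(np.isfinite(vals)):
        raise RuntimeError("score likelihood not finite on the search grid")
    i = int(np.argmin(vals))
    lo_b = xs[max(i - 1, 0)]
    hi_b = xs[min(i + 1, n_grid - 1)]
    res = minimize_scalar(neg_fun, bounds=(lo_b, hi_b), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:  # pragma: no cover - bounded Brent essentially always succeeds
        raise RuntimeError(f"score optimization failed: {res.message}")
    if res.fun <= vals[i]:
        return float(res.x), float(-res.fun)
    return float(xs[i]), float(-vals[i])


class _AdmLikelihood:
    """Case-only binomial likelihood for the ancestry odds ratio lambda."""

    def __init__(self, a_cases, theta_cases):
        a = np.asarray(a_cases, dtype=float)
        th = np.asarray(theta_cases, dtype=float)
        if a.shape != th.shape:
            raise ValueError("ancestry counts and theta must align")
        informative = (th > 0.0) & (th < 1.0)
        self.a = a[informative]
        self.theta = th[informative]
        if self.a.size == 0:
            raise ValueError("no informative cases (all theta at 0 or 1)")

    def loglik(self, lam: float) -> float:
        pi = lam * self.theta / (lam * self.theta + 1.0 - self.theta)
        pi = np.clip(pi, 1e-12, 1 - 1e-12)
        return float(np.sum(self.a * np.log(pi) + (2.0 - self.a) * np.log1p(-pi)))


class _Snp1Likelihood:
    """Retrospective allelic likelihood conditional on local ancestry.

    Individuals are aggregated into (status, ancestry count, genotype) cells;
    control cells do not depend on r but are kept so that nested likelihoods
    share the same data.
    """

    _LOGIT_LO, _LOGIT_HI = np.log(1e-6 / (1 - 1e-6)), np.log((1 - 1e-6) / 1e-6)

    def __init__(self, genotypes, local_ancestry, status):
        g = np.asarray(genotypes, dtype=float)
        a = np.asarray(local_ancestry)
        y = np.asarray(status)
        keep = ~np.isnan(g)
        self.g, self.a, self.y = g[keep].astype(int), a[keep], y[keep]
        if self.g.size == 0 or np.all(self.g == self.g[0]):
            raise ValueError("marker is monomorphic or fully missing")
        self.cells = np.zeros((2, 3, 3))
        np.add.at(self.cells, (self.y, self.a, self.g), 1.0)
        self.n_cases = int(self.cells[1].sum())
        self.n_controls = int(self.cells[0].sum())

    @staticmethod
    def _case_freq(p: float, r: float) -> float:
        return p * r / (1.0 + (r - 1.0) * p)

    def loglik(self, r: float, p_afr: float, p_eur: float) -> float:
        ll = 0.0
        for s in (0, 1):
            u_a = self._case_freq(p_afr, r) if s == 1 else p_afr
            u_e = self._case_freq(p_eur, r) if s == 1 else p_eur
            probs = np.empty((3, 3))
            for u, row in ((u_e, 0), (u_a, 2)):
                probs[row] = [(1 - u) ** 2, 2 * u * (1 - u), u * u]
            probs[1] = [(1 - u_a) * (1 - u_e), u_a + u_e - 2 * u_a * u_e, u_a * u_e]
            ll += float(np.sum(self.cells[s] * np.log(np.maximum(probs, _TINY))))
        return ll

    def null_freqs(self) -> tuple[float, float]:
        """Restricted (r = 1) ML frequencies: cases and controls pooled."""
        return estimate_ancestral_freqs(self.g, self.a, self.y, controls_only=False)

    def profile_max(self, extra_loglik=None,
                    p_start: tuple[float, float] | None = None) -> tuple[float, float]:
        """Maximize over (log r, logit p_afr, logit p_eur), optionally adding
        a term ``extra_loglik(r, p_afr, p_eur)`` (used by MIX for the
        ancestry piece, whose induced lambda depends on all three).

        Multi-start quasi-Newton over a bracketing set of r values; returns
        (log r at the maximum, maximized log likelihood).
        """
        from scipy.optimize import minimize

        if p_start is None:
            p_start = self.null_freqs()
        q0 = [float(np.log(p / (1 - p))) for p in np.clip(p_start, 1e-6, 1 - 1e-6)]

        def neg(vec):
            r = float(np.exp(vec[0]))
            pa = 1.0 / (1.0 + np.exp(-vec[1]))
            pe = 1.0 / (1.0 + np.exp(-vec[2]))
            val = self.loglik(r, pa, pe)
            if extra_loglik is not None:
                val += extra_loglik(r, pa, pe)
            return -val

        bounds = [(_LOG_R_LO, _LOG_R_HI),
                  (self._LOGIT_LO, self._LOGIT_HI), (self._LOGIT_LO, self._LOGIT_HI)]
        best = None
        for log_r0 in (np.log(0.2), 0.0, np.log(5.0)):
            res = minimize(neg, np.array([log_r0, *q0]), method="L-BFGS-B",
                           bounds=bounds, options={"ftol": 1e-13, "gtol": 1e-9,
                                                   "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):  # pragma: no cover
            raise RuntimeError("profile likelihood optimization failed")
        return float(best.x[0]), float(-best.fun)


def induced_ancestry_or(r: float, p_afr: float, p_eur: float) -> float:
    """Ancestry odds ratio induced at a locus by a single causal allele with
    allelic odds ratio r and ancestral frequencies (p_afr, p_eur)."""
    return (1.0 + (r - 1.0) * p_afr) / (1.0 + (r - 1.0) * p_eur)


# ---------------------------------------------------------------------------
# the four scores
# ---------------------------------------------------------------------------

def adm_score(case_ancestry_counts, case_global_theta) -> tuple[float, float, float]:
    """Affected-only admixture score: LRT of lambda = 1.  Returns
    (statistic, p, lambda_hat)."""
    lik = _AdmLikelihood(case_ancestry_counts, case_global_theta)
    ll0 = lik.loglik(1.0)
    x, ll1 = _maximize_scalar(lambda x: -lik.loglik(np.exp(x)))
    stat = max(2.0 * (ll1 - ll0), 0.0)
    return stat, float(chi2.sf(stat, 1)), float(np.exp(x))


def _check_plugin_freqs(p_afr: float, p_eur: float) -> None:
    if (p_afr in (0.0, 1.0)) and (p_eur in (0.0, 1.0)):
        raise ValueError("degenerate ancestral frequencies on both backgrounds")


def snp1_score(genotypes, local_ancestry, status, p_afr: float | None = None,
               p_eur: float | None = None) -> tuple[float, float, float]:
    """Ancestry-conditional allelic score: LRT of r = 1.  Returns
    (statistic, p, r_hat).

    With ``p_afr``/``p_eur`` supplied they are treated as known and only r is
    estimated; by default the ancestral frequencies are nuisance parameters
    and the test is a profile LRT, which keeps the null distribution
    chi-square when the frequencies must be estimated from the same sample.
    """
    lik = _Snp1Likelihood(genotypes, local_ancestry, status)
    if p_afr is not None and p_eur is not None:
        _check_plugin_freqs(p_afr, p_eur)
        ll0 = lik.loglik(1.0, p_afr, p_eur)
        x, ll1 = _maximize_scalar(lambda x: -lik.loglik(np.exp(x), p_afr, p_eur))
    else:
        pa0, pe0 = lik.null_freqs()
        ll0 = lik.loglik(1.0, pa0, pe0)
        x, ll1 = lik.profile_max(p_start=(pa0, pe0))
    stat = max(2.0 * (ll1 - ll0), 0.0)
    return stat, float(chi2.sf(stat, 1)), float(np.exp(x))


def mix_score(genotypes, local_ancestry, theta, status, p_afr: float | None = None,
              p_eur: float | None = None) -> tuple[float, float, float]:
    """Single-causal joint score: LRT along the curve lambda = lambda(r).
    Returns (statistic, p, r_hat_constrained).

    Frequencies supplied -> plug-in; omitted -> profiled as in
    :func:`snp1_score`.  The ancestry piece uses the constrained
    lambda(r) computed from the (current) frequencies.
    """
    y = np.asarray(status)
    adm_lik = _AdmLikelihood(np.asarray(local_ancestry)[y == 1],
                             np.asarray(theta)[y == 1])
    snp_lik = _Snp1Likelihood(genotypes, local_ancestry, status)
    if p_afr is not None and p_eur is not None:
        _check_plugin_freqs(p_afr, p_eur)

        def joint(log_r: float) -> float:
            r = float(np.exp(log_r))
            return (adm_lik.loglik(induced_ancestry_or(r, p_afr, p_eur))
                    + snp_lik.loglik(r, p_afr, p_eur))

        ll0 = joint(0.0)
        x, ll1 = _maximize_scalar(lambda x: -joint(x))
    else:
        pa0, pe0 = snp_lik.null_freqs()
        ll0 = adm_lik.loglik(1.0) + snp_lik.loglik(1.0, pa0, pe0)
        x, ll1 = snp_lik.profile_max(
            extra_loglik=lambda r, pa, pe: adm_lik.loglik(
                induced_ancestry_or(r, pa, pe)),
            p_start=(pa0, pe0))
    stat = max(2.0 * (ll1 - ll0), 0.0)
    return stat, float(chi2.sf(stat, 1)), float(np.exp(x))


def diff_score(adm_stat, snp1_stat: float | None = None,
               mix_stat: float | None = None,
               tol: float = 1e-8) -> tuple[float, float]:
    """DIFF = ADM + SNP1 - MIX, the 1-df test of the single-causal constraint.

    Accepts either the three statistics or an :class:`AdmixtureScoreSet`.
    """
    if isinstance(adm_stat, AdmixtureScoreSet):
        s = adm_stat
        adm_stat, snp1_stat, mix_stat = s.adm_stat, s.snp1_stat, s.mix_stat
    stat = adm_stat + snp1_stat - mix_stat
    if stat < -tol:
        raise ValueError(
            f"DIFF = {stat:.3g} < 0: scores were not computed on nested likelihoods")
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, 1))


def admixture_scores(genotypes, local_ancestry, theta, status,
                     p_afr: float | None = None, p_eur: float | None = None,
                     marker_id: str = "") -> AdmixtureScoreSet:
    """Compute the full ADM/SNP1/MIX/DIFF set for one marker.

    When ``p_afr``/``p_eur`` are omitted the ancestral frequencies are
    profiled (and the reported values are the null-restricted ML estimates);
    when supplied they are treated as known.  All four statistics are
    evaluated on the same individuals so the DIFF identity is exact.
    """
    g = np.asarray(genotypes, dtype=float)
    a = np.asarray(local_ancestry)
    th = np.asarray(theta, dtype=float)
    y = np.asarray(status)
    if not (g.shape == a.shape == th.shape == y.shape):
        raise ValueError("genotypes, ancestry, theta and status must align")
    supplied = p_afr is not None and p_eur is not None
    adm_stat, adm_p, lam_hat = adm_score(a[y == 1], th[y == 1])
    if supplied:
        snp1_stat, snp1_p, r_hat = snp1_score(g, a, y, p_afr, p_eur)
        mix_stat, mix_p, r_mix = mix_score(g, a, th, y, p_afr, p_eur)
    else:
        keep = ~np.isnan(g)
        p_afr, p_eur = estimate_ancestral_freqs(g[keep], a[keep], y[keep],
                                                controls_only=False)
        snp1_stat, snp1_p, r_hat = snp1_score(g, a, y)
        mix_stat, mix_p, r_mix = mix_score(g, a, th, y)
    # the constrained optimum cannot exceed the unconstrained one; clip the
    # sub-1e-8 numerical overshoot so the DIFF identity is exact
    mix_stat = min(mix_stat, adm_stat + snp1_stat)
    d_stat, d_p = diff_score(adm_stat, snp1_stat, mix_stat)
    return AdmixtureScoreSet(
        marker_id=marker_id, adm_stat=adm_stat, adm_p=adm_p,
        snp1_stat=snp1_stat, snp1_p=snp1_p, mix_stat=mix_stat, mix_p=mix_p,
        diff_stat=d_stat, diff_p=d_p, lam_hat=lam_hat, r_hat=r_hat, r_mix=r_mix,
        p_afr=float(p_afr), p_eur=float(p_eur),
        n_cases=int(np.sum(y == 1)), n_controls=int(np.sum(y == 0)),
    )


def cohort_scores(cohort: AdmixedCohort, marker: str | int,
                  p_afr: float | None = None,
                  p_eur: float | None = None) -> AdmixtureScoreSet:
    """Score one cohort marker, using stored theta and case status."""
    m = marker if isinstance(marker, (int, np.integer)) else cohort.marker_index(marker)
    return admixture_scores(
        cohort.genotypes[:, m], cohort.local_ancestry[:, m], cohort.theta,
        cohort.status, p_afr, p_eur, marker_id=str(cohort.markers["marker_id"][m]))


def averaged_mix(cohort: AdmixedCohort, marker: str | int,
                 n_samples: int = 100, subsample_sizes: tuple[int, int] = (933, 846),
                 rng: np.random.Generator | None = None,
                 relationship=None) -> AdmixtureScoreSet:
    """MIX/DIFF by averaging over random subsamples of unrelated subjects.

    The retrospective scores assume unrelated cases and controls; from the
    unrelated pool (relationship < 0.125, pedigree-based by default)
    ``n_samples`` independent draws of (n_cases, n_controls) are scored and
    the statistics averaged; p-values come from the averaged statistics.
    """
    rng = np.random.default_rng() if rng is None else rng
    m = marker if isinstance(marker, (int, np.integer)) else cohort.marker_index(marker)
    if relationship is None:
        relationship = kin.pedigree_relationship(kin.Pedigree.from_samples(cohort.samples))
    pool_ids = set(kin.unrelated_subset(relationship))
    ids = cohort.samples["id"].astype(str)
    in_pool = ids.isin(pool_ids).to_numpy()
    case_rows = np.flatnonzero(in_pool & (cohort.status == 1))
    ctrl_rows = np.flatnonzero(in_pool & (cohort.status == 0))
    n_cases, n_controls = subsample_sizes
    if case_rows.size < n_cases or ctrl_rows.size < n_controls:
        raise ValueError(
            f"unrelated pool has {case_rows.size} cases / {ctrl_rows.size} controls; "
            f"requested ({n_cases}, {n_controls})")
    fields = ("adm_stat", "snp1_stat", "mix_stat", "diff_stat",
              "lam_hat", "r_hat", "r_mix", "p_afr", "p_eur")
    acc = {f: 0.0 for f in fields}
    for _ in range(n_samples):
        rows = np.concatenate([rng.choice(case_rows, n_cases, replace=False),
                               rng.choice(ctrl_rows, n_controls, replace=False)])
        s = admixture_scores(cohort.genotypes[rows, m], cohort.local_ancestry[rows, m],
                             cohort.theta[rows], cohort.status[rows],
                             marker_id=str(cohort.markers["marker_id"][m]))
        for f in fields:
            acc[f] += getattr(s, f)
    avg = {f: acc[f] / n_samples for f in fields}
    d_stat = max(avg["adm_stat"] + avg["snp1_stat"] - avg["mix_stat"], 0.0)
    return AdmixtureScoreSet(
        marker_id=str(cohort.markers["marker_id"][m]),
        adm_stat=avg["adm_stat"], adm_p=float(chi2.sf(avg["adm_stat"], 1)),
        snp1_stat=avg["snp1_stat"], snp1_p=float(chi2.sf(avg["snp1_stat"], 1)),
        mix_stat=avg["mix_stat"], mix_p=float(chi2.sf(avg["mix_stat"], 1)),
        diff_stat=d_stat, diff_p=float(chi2.sf(d_stat, 1)),
        lam_hat=avg["lam_hat"], r_hat=avg["r_hat"], r_mix=avg["r_mix"],
        p_afr=avg["p_afr"], p_eur=avg["p_eur"],
        n_cases=n_cases, n_controls=n_controls,
    )


# ---------------------------------------------------------------------------
# region definition and screening
# ---------------------------------------------------------------------------

def region_boundaries(marker_positions, adm_pvalues,
                      alpha: float = 0.05) -> tuple[int, int] | None:
    """Closed interval spanned by the first and last marker with affected-only
    admixture p < alpha; None when no marker qualifies."""
    pos = np.asarray(marker_positions)
    p = np.asarray(adm_pvalues, dtype=float)
    if pos.shape != p.shape:
        raise ValueError("positions and p-values must have equal length")
    if np.any(np.diff(pos) < 0):
        raise ValueError("marker positions must be sorted")
    hits = np.flatnonzero(p < alpha)
    if hits.size == 0:
        return None
    return int(pos[hits[0]]), int(pos[hits[-1]])


def tiered_screen(assoc_pvalues: dict, confounding_ratios: dict,
                  p_threshold: float = 0.05,
                  confounding_threshold: float = 0.15) -> list:
    """Markers that enter MIX testing: unadjusted association p < p_threshold
    and local-ancestry confounding ratio < confounding_threshold."""
    out = []
    for marker, p in assoc_pvalues.items():
        cr = confounding_ratios.get(marker)
        if cr is None:
            continue
        if p < p_threshold and cr < confounding_threshold:
            out.append(marker)
    return out
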