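"""Heritability of liability from local ancestry (or genotypes).

The model is the standard single-component GREML: for phenotype vector y
(0/1 case status analysed on the observed scale) with fixed effects X
(intercept, global ancestry, sex),

    y = X b + g + e,   g ~ N(0, sigma2_a * A),   e ~ N(0, sigma2_e * I),

where A is a relationship matrix.  For the ancestry analysis A is built from
diploid African-allele counts standardized exactly like genotype dosages:
the count a_jm replaces the genotype, with locus mean 2*pbar_m and variance
2*pbar_m*(1-pbar_m).  REML is fit by average information (AI) iterations
with EM fallback; the observed-scale heritability sigma2_a / (sigma2_a +
sigma2_e) is transformed to the liability scale with the threshold-model
ascertainment correction using the population prevalence K and the sample
case proportion P.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .cohort import AdmixedCohort


@dataclass
class RelationshipMatrix:
    """Symmetric n x n relationship matrix with its provenance."""

    values: np.ndarray
    source: str                      #: "ancestry" or "genotype"
    n_markers: int
    ids: list | None = None
    excluded_regions: list = field(default_factory=list)
    standardized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("relationship matrix has non-finite entries")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")

    @cached_property
    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (eigenvalues, eigenvectors)."""
        w, u = np.linalg.eigh((self.values + self.values.T) / 2.0)
        return np.maximum(w, 0.0), u

    def to_tsv(self, path) -> None:
        ids = self.ids or list(range(self.values.shape[0]))
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(path, sep="\t")


@dataclass
class VarianceComponents:
    """REML fit summary on the observed and liability scales."""

    sigma2_a: float
    sigma2_e: float
    h2_obs: float
    h2_se: float
    h2_liab: float
    prevalence: float
    case_proportion: float
    lrt_stat: float
    lrt_p: float
    loglik: float
    n: int
    n_iter: int
    converged: bool


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def _standardized_grm(dosage: np.ndarray, source: str, standardized: bool,
                      keep: np.ndarray, ids=None) -> RelationshipMatrix:
    d = dosage[:, keep].astype(float)
    if d.shape[1] == 0:
        raise ValueError("no variable markers left to build the matrix")
    p = np.nanmean(d, axis=0) / 2.0
    centered = d - 2.0 * p
    centered = np.where(np.isnan(centered), 0.0, centered)  # mean-impute missing
    if standardized:
        z = centered / np.sqrt(2.0 * p * (1.0 - p))
    else:
        z = centered
    a = (z @ z.T) / z.shape[1]
    return RelationshipMatrix(values=a, source=source, n_markers=z.shape[1],
                              ids=ids, standardized=standardized)


def ancestry_grm(local_ancestry: np.ndarray, standardized: bool = True,
                 ids=None, marker_mask=None) -> RelationshipMatrix:
    """Relationship matrix from diploid African-allele counts.

    A_jk = (1/M) sum_m (a_jm - 2 pbar_m)(a_km - 2 pbar_m) / (2 pbar_m (1 - pbar_m))
    with pbar_m the sample mean African ancestry proportion at marker m;
    zero-variance markers are dropped from M.
    """
    a = np.asarray(local_ancestry, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need a (n >= 2, M) local-ancestry matrix")
    keep = np.nanstd(a, axis=0) > 0
    if marker_mask is not None:
        keep &= np.asarray(marker_mask, dtype=bool)
    if not keep.any():
        raise ValueError("no markers with ancestry variance")
    return _standardized_grm(a, "ancestry", standardized, keep, ids)


def genotype_grm(genotypes: np.ndarray, maf_floor: float = 0.01,
                 ids=None, marker_mask=None) -> RelationshipMatrix:
    """Allele-frequency-standardized GRM over markers with MAF > maf_floor."""
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need a (n >= 2, M) genotype matrix")
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = np.nan_to_num(maf) > maf_floor
    if marker_mask is not None:
        keep &= np.asarray(marker_mask, dtype=bool)
    if not keep.any():
        raise ValueError(f"no markers with MAF > {maf_floor}")
    return _standardized_grm(g, "genotype", True, keep, ids)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _reml_quantities(yt, xt, w, s2a, s2e):
    """Log restricted likelihood and P-projections in the eigenbasis of A."""
    v = s2a * w + s2e
    vi = 1.0 / v
    xtv = xt * vi[:, None]
    xvx = xt.T @ xtv
    xvx_inv = np.linalg.inv(xvx)
    beta = xvx_inv @ (xtv.T @ yt)
    resid = yt - xt @ beta
    py = resid * vi
    ll = -0.5 * (np.sum(np.log(v)) + np.linalg.slogdet(xvx)[1] + float(yt @ py))
    return ll, py, vi, xtv, xvx_inv


def _trace_p_diag(d, vi, xtv, xvx_inv):
    """tr(P diag(d)) for P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 (eigenbasis)."""
    t1 = float(np.sum(d * vi))
    m = xtv.T @ (xtv * d[:, None])
    return t1 - float(np.trace(xvx_inv @ m))


def reml_fit(y: np.ndarray, covariates: np.ndarray | None,
             grm: RelationshipMatrix, prevalence: float = 0.001,
             max_iter: int = 200, tol: float = 1e-8,
             constrain: bool = True) -> VarianceComponents:
    """Single-component AI-REML on the observed scale with liability transform.

    Fixed effects are an intercept plus the supplied covariates.  AI updates
    are safeguarded: any step leaving the parameter space falls back to an
    EM step, and variances are floored at 1e-6 of the phenotypic variance.
    The LRT compares against sigma2_a = 0 (closed-form OLS residual fit).

    With ``constrain=False`` the genetic variance may go negative (the
    residual variance stays positive and V is kept positive definite), which
    removes the boundary-truncation bias of the constrained estimator — the
    standard choice when averaging estimates over replicates.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    x = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)])
    if n <= x.shape[1] + 1:
        raise ValueError("more fixed effects than informative observations")
    if grm.values.shape[0] != n:
        raise ValueError("GRM dimension does not match phenotype length")
    if np.allclose(grm.values, np.eye(n), atol=1e-12):
        raise ValueError("GRM equals the identity: variance components are not identifiable")

    w, u = grm.eig
    yt, xt = u.T @ y, u.T @ x
    vary = float(np.var(y, ddof=1))
    floor = 1e-6 * vary
    s2a, s2e = 0.5 * vary, 0.5 * vary

    ll, py, vi, xtv, xvx_inv = _reml_quantities(yt, xt, w, s2a, s2e)
    converged = False
    it = 0
    ll_best = ll
    stall = 0
    for it in range(1, max_iter + 1):
        # first derivatives: dl/ds2_i = -0.5 [tr(P V_i) - y'P V_i P y]
        apy = w * py
        tr_pa = _trace_p_diag(w, vi, xtv, xvx_inv)
        tr_pi = _trace_p_diag(np.ones(n), vi, xtv, xvx_inv)
        # quadratic forms y'P V_i P y; note P y is `py` in the eigenbasis
        papy = _project(apy, vi, xtv, xvx_inv)
        pipy = _project(py, vi, xtv, xvx_inv)
        grad = 0.5 * np.array([float(py @ apy) - tr_pa,
                               float(py @ py) - tr_pi])
        ai = 0.5 * np.array([
            [float(apy @ papy), float(apy @ pipy)],
            [float(apy @ pipy), float(py @ pipy)],
        ])
        # a component pinned at its floor with a negative gradient stays there
        # (boundary maximum); update only the free component
        at_floor = np.array([constrain and s2a <= floor * (1 + 1e-9) and grad[0] < 0,
                             s2e <= floor * (1 + 1e-9) and grad[1] < 0])
        try:
            if at_floor.any():
                step = np.zeros(2)
                free = ~at_floor
                step[free] = grad[free] / np.maximum(np.diag(ai)[free], 1e-300)
            else:
                step = np.linalg.solve(ai, grad)
        except np.linalg.LinAlgError:
            step = None
        w_max = float(w.max())

        def _clamp(cand: np.ndarray) -> np.ndarray:
            out = cand.copy()
            out[1] = max(out[1], floor)
            if constrain:
                out[0] = max(out[0], floor)
            else:  # keep V = s2a*A + s2e*I positive definite
                out[0] = max(out[0], -0.95 * out[1] / max(w_max, 1e-12))
            return out

        new = None
        if step is not None:
            cand = np.array([s2a, s2e]) + step
            if np.all(np.isfinite(cand)):
                new = _clamp(cand)
        if new is None:  # EM fallback
            new = _clamp(np.array([
                s2a + (s2a ** 2) * (float(py @ apy) - tr_pa) / n,
                s2e + (s2e ** 2) * (float(py @ py) - tr_pi) / n,
            ]))
        ll_new, py_n, vi_n, xtv_n, xvx_inv_n = _reml_quantities(yt, xt, w, new[0], new[1])
        # step-halve toward the current point if the likelihood got worse
        halves = 0
        while ll_new < ll - 1e-10 and halves < 20:
            new = 0.5 * (new + np.array([s2a, s2e]))
            ll_new, py_n, vi_n, xtv_n, xvx_inv_n = _reml_quantities(yt, xt, w, new[0], new[1])
            halves += 1
        delta = abs(ll_new - ll)
        param_move = float(np.max(np.abs(new - np.array([s2a, s2e]))))
        s2a, s2e = float(new[0]), float(new[1])
        ll, py, vi, xtv, xvx_inv = ll_new, py_n, vi_n, xtv_n, xvx_inv_n
        # stall detection: repeated failure to improve the best likelihood
        # (oscillation on a flat ridge) counts as convergence
        if ll > ll_best + tol:
            ll_best = ll
            stall = 0
        else:
            stall += 1
        if delta < tol or param_move < 1e-9 * vary or stall >= 5:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"REML did not converge in {max_iter} iterations (loglik {ll:.6f}, "
            f"sigma2_a {s2a:.3g}, sigma2_e {s2e:.3g})")

    # SE of h2_obs by the delta method on the inverse AI (information) matrix
    apy = w * py
    papy = _project(apy, vi, xtv, xvx_inv)
    pipy = _project(py, vi, xtv, xvx_inv)
    ai = 0.5 * np.array([
        [float(apy @ papy), float(apy @ pipy)],
        [float(apy @ pipy), float(py @ pipy)],
    ])
    total = s2a + s2e
    h2 = s2a / total
    try:
        ai_inv = np.linalg.inv(ai)
        grad_h = np.array([s2e, -s2a]) / total ** 2
        h2_se = float(np.sqrt(max(grad_h @ ai_inv @ grad_h, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        h2_se = float("nan")
    # null model: sigma2_a = 0, OLS residual variance (REML closed form)
    q, _ = np.linalg.qr(x)
    r0 = y - q @ (q.T @ y)
    df = n - x.shape[1]
    s2e0 = float(r0 @ r0) / df
    xvx0 = (x.T @ x) / s2e0
    ll0 = -0.5 * (n * np.log(s2e0) + np.linalg.slogdet(xvx0)[1] + df)
    lrt = max(2.0 * (ll - ll0), 0.0)
    p = float(chi2.sf(lrt, 1))
    case_prop = float(np.mean(y)) if set(np.unique(y)) <= {0.0, 1.0} else float("nan")
    h2_liab = (liability_transform(h2, prevalence, case_prop)
               if np.isfinite(case_prop) and 0.0 <= h2 <= 1.0 else float("nan"))
    return VarianceComponents(
        sigma2_a=s2a, sigma2_e=s2e, h2_obs=h2, h2_se=h2_se, h2_liab=h2_liab,
        prevalence=prevalence, case_proportion=case_prop, lrt_stat=lrt, lrt_p=p,
        loglik=float(ll), n=n, n_iter=it, converged=converged)


def _project(v, vi, xtv, xvx_inv):
    """Apply P (in the eigenbasis) to a vector."""
    return v * vi - xtv @ (xvx_inv @ (xtv.T @ v))


def liability_transform(h2_obs: float, K: float, P: float) -> float:
    """Observed-scale to liability-scale heritability for ascertained case-control data.

    h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P)) with z the standard normal
    density at the threshold Phi^-1(1-K).  Capped at 1 with a warning.
    """
    if not 0 < K < 1 or not 0 < P < 1:
        raise ValueError("prevalence K and case proportion P must be in (0, 1)")
    if not 0 <= h2_obs <= 1:
        raise ValueError("h2_obs must be in [0, 1]")
    z = norm.pdf(norm.ppf(1.0 - K))
    out = h2_obs * K ** 2 * (1.0 - K) ** 2 / (z ** 2 * P * (1.0 - P))
    if out > 1.0:
        import warnings
        warnings.warn(f"liability-scale h2 = {out:.3f} capped at 1", stacklevel=2)
        return 1.0
    return float(out)


# ---------------------------------------------------------------------------
# cohort-level drivers
# ---------------------------------------------------------------------------

def _cohort_inputs(cohort: AdmixedCohort):
    y = cohort.status.astype(float)
    covs = np.column_stack([cohort.theta, (cohort.sex == 2).astype(float)])
    return y, covs


def cohort_grm(cohort: AdmixedCohort, source: str = "ancestry",
               marker_mask=None, standardized: bool = True) -> RelationshipMatrix:
    ids = list(cohort.samples["id"].astype(str))
    if source == "ancestry":
        return ancestry_grm(cohort.local_ancestry, standardized, ids, marker_mask)
    if source == "genotype":
        return genotype_grm(cohort.genotypes, ids=ids, marker_mask=marker_mask)
    raise ValueError("source must be 'ancestry' or 'genotype'")


def heritability(cohort: AdmixedCohort, source: str = "ancestry",
                 prevalence: float = 0.001, marker_mask=None) -> VarianceComponents:
    y, covs = _cohort_inputs(cohort)
    grm = cohort_grm(cohort, source, marker_mask)
    return reml_fit(y, covs, grm, prevalence)


def drop_region_heritability(cohort: AdmixedCohort, source: str,
                             region: tuple[int, int] | None,
                             prevalence: float = 0.001,
                             ) -> tuple[VarianceComponents, VarianceComponents]:
    """Heritability with and without the markers inside a closed [start, end]
    interval; returns (full fit, region-removed fit)."""
    full = heritability(cohort, source, prevalence)
    if region is None:
        return full, full
    pos = cohort.markers["pos"].to_numpy()
    outside = (pos < region[0]) | (pos > region[1])
    if not outside.any():
        raise ValueError("region covers every marker; nothing left to fit")
    dropped = heritability(cohort, source, prevalence, marker_mask=outside)
    return full, dropped


def subgroup_heritability(cohort: AdmixedCohort, subgroup: str,
                          source: str = "ancestry",
                          prevalence: float = 0.001) -> VarianceComponents:
    """REML for one case subphenotype versus all controls, with the sample
    case proportion recomputed for that contrast."""
    sub = cohort.samples["subphenotype"].to_numpy()
    is_case_sub = (cohort.status == 1) & (sub == subgroup)
    if subgroup == "all":
        is_case_sub = cohort.status == 1
    if not is_case_sub.any():
        raise ValueError(f"no cases with subphenotype {subgroup!r}")
    mask = is_case_sub | (cohort.status == 0)
    return heritability(cohort.subset(mask), source, prevalence)
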