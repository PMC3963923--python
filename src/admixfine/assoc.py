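"""Ancestry-aware single-marker association and conditional modelling.

All fits are logistic GEE with an independence working correlation and a
cluster-robust (sandwich) covariance, treating each family as a cluster so
related individuals can be analysed without a mixed model.  Every model
includes global African ancestry (theta) and sex; local-ancestry adjustment
adds the diploid African-allele count at the tested marker.  Odds ratios are
per copy of the coded allele under a multiplicative (log-additive) model,
with Wald confidence intervals exp(beta +/- 1.96 SE).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .cohort import AdmixedCohort

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class GEEFit:
    params: pd.Series
    robust_se: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    n_obs: int
    n_clusters: int


@dataclass
class AssociationResult:
    """One marker's GEE association summary."""

    marker_id: str
    coded_allele: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float
    adjusted_local_ancestry: bool
    covariates: list[str] = field(default_factory=list)
    n_individuals: int = 0
    n_clusters: int = 0
    f_case: float = float("nan")
    f_control: float = float("nan")


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")


def _check_separation(X: pd.DataFrame, fit: GEEFit) -> None:
    # a coefficient this large on a standardized column means quasi-separation
    scale = X.std(ddof=0).replace(0.0, 1.0)
    z = (fit.params * scale).drop("const", errors="ignore").abs()
    if len(z) and z.max() > 15.0:
        raise ValueError(f"perfect separation suspected for column {z.idxmax()!r}")


def gee_logistic(y: np.ndarray, X: pd.DataFrame, clusters: np.ndarray,
                 small_sample_correction: bool = False) -> GEEFit:
    """Logistic GEE with independence working correlation and sandwich covariance.

    With singleton clusters this reduces to the ordinary logistic MLE with a
    heteroskedasticity-robust covariance.  ``small_sample_correction``
    applies the G/(G-1) cluster degrees-of-freedom inflation to the
    covariance (off by default).
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float).reset_index(drop=True)
    clusters = np.asarray(clusters)
    if len(y) != len(X) or len(y) != len(clusters):
        raise ValueError("y, X and clusters must have equal length")
    _check_design(X)
    model = sm.GEE(y, X, groups=clusters, family=sm.families.Binomial(),
                   cov_struct=sm.cov_struct.Independence())
    res = model.fit(maxiter=200)
    n_clusters = int(pd.unique(clusters).size)
    cov = np.asarray(res.cov_params())
    se = res.bse.copy()
    pvalues = res.pvalues.copy()
    if small_sample_correction and n_clusters > 1:
        factor = n_clusters / (n_clusters - 1.0)
        cov = cov * factor
        se = se * np.sqrt(factor)
        z = res.params / se
        pvalues = pd.Series(2.0 * norm.sf(np.abs(z)), index=res.params.index)
    fit = GEEFit(params=res.params, robust_se=se, pvalues=pvalues,
                 cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
                 n_obs=int(len(y)), n_clusters=n_clusters)
    _check_separation(X, fit)
    return fit


def _base_design(cohort: AdmixedCohort, rows: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "const": 1.0,
        "theta": cohort.theta[rows],
        "sex": (cohort.sex[rows] == 2).astype(float),  # female indicator
    })


def _coded_dosage(cohort: AdmixedCohort, m: int) -> tuple[np.ndarray, str]:
    """Return the marker's dosage coded to the cohort minor allele."""
    g = cohort.genotypes[:, m]
    obs = g[~np.isnan(g)]
    if obs.size == 0 or obs.min() == obs.max():
        raise ValueError(f"marker {cohort.markers['marker_id'][m]!r} is monomorphic")
    allele = str(cohort.markers["alt"][m])
    if obs.mean() / 2.0 > 0.5:
        g = 2.0 - g
        allele = str(cohort.markers["ref"][m])
    return g, allele


def snp_association(cohort: AdmixedCohort, marker: str | int,
                    adjust_local_ancestry: bool = False,
                    extra_covariates: pd.DataFrame | None = None) -> AssociationResult:
    """Single-marker GEE association of case status on coded-allele dosage.

    Individuals missing the tested genotype are dropped for this marker only.
    """
    m = marker if isinstance(marker, (int, np.integer)) else cohort.marker_index(marker)
    g, allele = _coded_dosage(cohort, m)
    rows = np.flatnonzero(~np.isnan(g))
    X = _base_design(cohort, rows)
    X.insert(1, "genotype", g[rows])
    if adjust_local_ancestry:
        X["local_ancestry"] = cohort.local_ancestry[rows, m].astype(float)
    if extra_covariates is not None:
        for c in extra_covariates.columns:
            X[c] = np.asarray(extra_covariates[c])[rows]
    y = cohort.status[rows]
    fit = gee_logistic(y, X, cohort.family[rows])
    beta = float(fit.params["genotype"])
    se = float(fit.robust_se["genotype"])
    return AssociationResult(
        marker_id=str(cohort.markers["marker_id"][m]), coded_allele=allele,
        odds_ratio=float(np.exp(beta)), ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)), p_value=float(fit.pvalues["genotype"]),
        beta=beta, se=se, adjusted_local_ancestry=adjust_local_ancestry,
        covariates=[c for c in X.columns if c not in ("const", "genotype")],
        n_individuals=fit.n_obs, n_clusters=fit.n_clusters,
        f_case=float(g[rows][y == 1].mean() / 2) if (y == 1).any() else float("nan"),
        f_control=float(g[rows][y == 0].mean() / 2) if (y == 0).any() else float("nan"),
    )


def confounding_ratio(beta_adjusted: float, beta_unadjusted: float) -> float:
    """Relative change in the log odds ratio after local-ancestry adjustment:
    |beta_adj - beta_unadj| / |beta_unadj|."""
    if beta_unadjusted == 0:
        raise ValueError("confounding ratio undefined for zero unadjusted log OR")
    return abs(beta_adjusted - beta_unadjusted) / abs(beta_unadjusted)


def stratified_or_by_ancestry(cohort: AdmixedCohort,
                              marker: str | int) -> dict[int, AssociationResult | None]:
    """Genotype odds ratio within each local-ancestry stratum (0/1/2 African alleles).

    A stratum that is empty or monomorphic is reported as None rather than
    raising.
    """
    m = marker if isinstance(marker, (int, np.integer)) else cohort.marker_index(marker)
    out: dict[int, AssociationResult | None] = {}
    for a in (0, 1, 2):
        mask = cohort.local_ancestry[:, m] == a
        if mask.sum() == 0:
            out[a] = None
            continue
        sub = cohort.subset(mask)
        try:
            out[a] = snp_association(sub, m, adjust_local_ancestry=False)
        except ValueError:
            out[a] = None
    return out


def la_association(cohort: AdmixedCohort, locus: str | int,
                   conditioning_markers: list | None = None) -> AssociationResult:
    """GEE association of case status on local-ancestry dosage at a locus,
    optionally conditioning on the genotypes of candidate causal markers."""
    m = locus if isinstance(locus, (int, np.integer)) else cohort.marker_index(locus)
    a = cohort.local_ancestry[:, m].astype(float)
    if a.min() == a.max():
        raise ValueError("local ancestry has zero variance at this locus")
    keep = np.ones(cohort.n_individuals, dtype=bool)
    cond_idx = [c if isinstance(c, (int, np.integer)) else cohort.marker_index(c)
                for c in (conditioning_markers or [])]
    for c in cond_idx:
        keep &= ~np.isnan(cohort.genotypes[:, c])
    rows = np.flatnonzero(keep)
    X = _base_design(cohort, rows)
    X.insert(1, "local_ancestry", a[rows])
    for c in cond_idx:
        X[f"g_{cohort.markers['marker_id'][c]}"] = cohort.genotypes[rows, c]
    fit = gee_logistic(cohort.status[rows], X, cohort.family[rows])
    beta = float(fit.params["local_ancestry"])
    se = float(fit.robust_se["local_ancestry"])
    return AssociationResult(
        marker_id=str(cohort.markers["marker_id"][m]), coded_allele="AFR",
        odds_ratio=float(np.exp(beta)), ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)), p_value=float(fit.pvalues["local_ancestry"]),
        beta=beta, se=se, adjusted_local_ancestry=False,
        covariates=[c for c in X.columns if c not in ("const", "local_ancestry")],
        n_individuals=fit.n_obs, n_clusters=fit.n_clusters,
    )


def ld_r2(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of genotype dosages."""
    a = np.asarray(genotypes_a, dtype=float)
    b = np.asarray(genotypes_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("both markers must be polymorphic on shared individuals")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def forward_select(cohort: AdmixedCohort, region_markers: list,
                   alpha: float = 0.05, max_steps: int = 10,
                   r2_guard: float = 0.99) -> list[tuple[str, AssociationResult]]:
    """Forward selection of conditionally significant markers within a region.

    At each step the candidate with the smallest conditional GEE p-value
    (conditioning on all previously selected genotypes) is added, stopping
    when the best p exceeds ``alpha`` or ``max_steps`` is reached.  Ties are
    broken by genomic position; candidates in near-perfect LD (r^2 >=
    ``r2_guard``) with a selected marker are skipped.
    """
    if not region_markers:
        raise ValueError("region_markers must be non-empty")
    idx = [m if isinstance(m, (int, np.integer)) else cohort.marker_index(m)
           for m in region_markers]
    selected: list[tuple[str, AssociationResult]] = []
    selected_idx: list[int] = []
    while len(selected) < max_steps:
        best: tuple[float, int, AssociationResult] | None = None
        for m in idx:
            if m in selected_idx:
                continue
            try:
                if any(ld_r2(cohort.genotypes[:, m], cohort.genotypes[:, s]) >= r2_guard
                       for s in selected_idx):
                    continue
                cond = pd.DataFrame(
                    {f"cond_{s}": np.nan_to_num(cohort.genotypes[:, s]) for s in selected_idx})
                res = snp_association(cohort, m, extra_covariates=cond if selected_idx else None)
            except ValueError:
                continue
            key = (res.p_value, int(cohort.markers["pos"][m]))
            if best is None or key < (best[0], int(cohort.markers["pos"][best[1]])):
                best = (res.p_value, m, res)
        if best is None or best[0] > alpha:
            break
        selected.append((str(cohort.markers["marker_id"][best[1]]), best[2]))
        selected_idx.append(best[1])
    return selected
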