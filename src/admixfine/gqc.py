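"""Marker and sample quality control for array / imputed genotype data.

Filters mirror a standard GWAS pipeline for an admixed case-control sample:
per-marker call rate, minor allele frequency, Hardy-Weinberg exact tests
stratified by case status, and differential case-control missingness; per
sample, low call rate, extreme heterozygosity and duplicate detection from
pairwise IBD.  Imputed genotypes are hardened from posterior probabilities
with an inclusive 0.9 threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact


@dataclass
class QCThresholds:
    """Filter thresholds; defaults reproduce the hard-call GWAS pipeline."""

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    hwe_p_cases: float = 1e-4
    hwe_p_controls: float = 1e-3
    diff_missing_p: float = 1e-3
    het_sd_bound: float = 5.0
    sample_min_call_rate: float = 0.90
    duplicate_ibd: float = 0.25
    posterior_threshold: float = 0.9
    min_info: float = 0.5  #: imputation info score, applied to a supplied column

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_cases", "hwe_p_controls",
                     "diff_missing_p", "sample_min_call_rate", "duplicate_ibd",
                     "posterior_threshold", "min_info"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.het_sd_bound <= 0:
            raise ValueError("het_sd_bound must be positive")


@dataclass
class QCReport:
    """Pass/fail table with failure reasons, one row per marker or sample."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_pass(self) -> int:
        return int(self.table["pass"].sum())

    def passing(self) -> list:
        return list(self.table.loc[self.table["pass"], self.table.columns[0]])

    def failing(self) -> list:
        return list(self.table.loc[~self.table["pass"], self.table.columns[0]])


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probability of all
    heterozygote configurations no more probable than the observed one
    (Wigginton-style enumeration via the heterozygote-count recurrence).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # heterozygote count has the parity of the rare allele count
    het_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if het_values.size == 1:
        return 1.0
    # unnormalized probabilities via the standard recurrence in het count h:
    # P(h+2)/P(h) = 4 * n_rare_hom(h) * n_common_hom(h) / ((h+2) * (h+1))
    logp = np.zeros(het_values.size)
    for i in range(1, het_values.size):
        h = int(het_values[i - 1])
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[i] = logp[i - 1] + math.log(4.0 * rare_hom * common_hom) \
            - math.log((h + 2.0) * (h + 1.0))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = n_het
    p_obs = p[het_values == obs][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def call_from_probabilities(posteriors, threshold: float = 0.9) -> float:
    """Harden one genotype from (P(0), P(1), P(2)); NaN if below threshold."""
    probs = np.asarray(posteriors, dtype=float)
    if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("posteriors must be three non-negative values summing to 1")
    best = int(np.argmax(probs))
    return float(best) if probs[best] >= threshold else float("nan")


def marker_qc(genotypes: np.ndarray, case_status: np.ndarray,
              thresholds: QCThresholds | None = None,
              marker_ids=None, info_scores=None) -> QCReport:
    """Per-marker QC: call rate, MAF, stratified HWE, differential missingness.

    A marker fails when call rate <= min_call_rate, MAF <= min_maf, the HWE
    exact p falls below the case or control floor, the 2x2 Fisher test of
    missingness by status falls below its floor, or (when ``info_scores`` is
    given) the precomputed imputation info score falls below min_info.
    """
    t = thresholds or QCThresholds()
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.size == 0:
        raise ValueError("genotypes must be a non-empty (n, M) matrix")
    y = np.asarray(case_status, dtype=int)
    if y.shape[0] != g.shape[0]:
        raise ValueError("case_status length must match genotype rows")
    n, m = g.shape
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(m)]
    rows = []
    for j in range(m):
        col = g[:, j]
        missing = np.isnan(col)
        call_rate = 1.0 - missing.mean()
        obs = col[~missing]
        reasons = []
        if call_rate <= t.min_call_rate:
            reasons.append("call_rate")
        maf = np.nan
        if obs.size:
            p_alt = obs.mean() / 2.0
            maf = min(p_alt, 1.0 - p_alt)
            if maf <= t.min_maf:
                reasons.append("maf")
            for label, mask, floor in (("cases", y == 1, t.hwe_p_cases),
                                       ("controls", y == 0, t.hwe_p_controls)):
                sub = col[mask & ~missing]
                if sub.size:
                    p_hwe = hwe_exact_test(int((sub == 0).sum()), int((sub == 1).sum()),
                                           int((sub == 2).sum()))
                    if p_hwe <= floor:
                        reasons.append(f"hwe_{label}")
        else:
            reasons.append("maf")
        n_miss_case = int((missing & (y == 1)).sum())
        n_miss_ctrl = int((missing & (y == 0)).sum())
        table = [[n_miss_case, int((y == 1).sum()) - n_miss_case],
                 [n_miss_ctrl, int((y == 0).sum()) - n_miss_ctrl]]
        p_dm = fisher_exact(table)[1]
        if p_dm <= t.diff_missing_p:
            reasons.append("differential_missingness")
        if info_scores is not None and info_scores[j] < t.min_info:
            reasons.append("info_score")
        rows.append({"marker_id": marker_ids[j], "pass": not reasons,
                     "reasons": ";".join(reasons), "call_rate": call_rate, "maf": maf})
    return QCReport(pd.DataFrame(rows))


def sample_qc(genotypes: np.ndarray, ibd: np.ndarray | None = None,
              thresholds: QCThresholds | None = None, sample_ids=None,
              family_ids=None) -> QCReport:
    """Per-sample QC: call rate, heterozygosity outliers, duplicate pairs.

    ``ibd`` is a symmetric matrix of pairwise IBD proportions (e.g. twice the
    KING kinship); pairs above ``duplicate_ibd`` that are not in the same
    declared family are treated as duplicates and the higher id is removed.
    The screen is applied cohort-wide unless ``family_ids`` exempts known
    relatives.
    """
    t = thresholds or QCThresholds()
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need a genotype matrix with at least two samples")
    n = g.shape[0]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n)]
    sample_ids = [str(s) for s in sample_ids]
    obs = ~np.isnan(g)
    call_rate = obs.mean(axis=1)
    with np.errstate(invalid="ignore"):
        het = np.nansum(g == 1, axis=1) / np.maximum(obs.sum(axis=1), 1)
    het_mean, het_sd = het.mean(), het.std(ddof=1)
    reasons = [[] for _ in range(n)]
    for j in range(n):
        if call_rate[j] < t.sample_min_call_rate:
            reasons[j].append("call_rate")
        if het_sd > 0 and abs(het[j] - het_mean) > t.het_sd_bound * het_sd:
            reasons[j].append("heterozygosity")
    if ibd is not None:
        ibd = np.asarray(ibd, dtype=float)
        for j in range(n):
            for k in range(j + 1, n):
                if family_ids is not None and family_ids[j] == family_ids[k]:
                    continue
                if ibd[j, k] > t.duplicate_ibd:
                    drop = j if sample_ids[j] > sample_ids[k] else k
                    if "duplicate" not in reasons[drop]:
                        reasons[drop].append("duplicate")
    rows = [{"sample_id": sample_ids[j], "pass": not reasons[j],
             "reasons": ";".join(reasons[j]), "call_rate": call_rate[j],
             "heterozygosity": het[j]} for j in range(n)]
    return QCReport(pd.DataFrame(rows))
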