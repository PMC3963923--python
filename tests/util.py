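"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (enumeration, linear scans, double
loops) so it cannot share a failure mode with the implementation it checks.
"""
from __future__ import annotations

from math import exp, lgamma, log

import numpy as np


def mode_lowest(values) -> int:
    """Brute-force modal value; ties -> smallest value."""
    vals = sorted(set(values))
    counts = {v: sum(1 for x in values if x == v) for v in vals}
    best = max(counts.values())
    return min(v for v in vals if counts[v] == best)


def nearest_scan(typed_pos, typed_anc, query) -> list:
    """Linear-scan nearest neighbour; exact ties -> lower position."""
    out = []
    for q in query:
        best_i, best_d = None, None
        for i, p in enumerate(typed_pos):
            d = abs(q - p)
            if best_d is None or d < best_d or (d == best_d and p < typed_pos[best_i]):
                best_i, best_d = i, d
        out.append(typed_anc[best_i])
    return out


def hwe_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p by direct evaluation of every heterozygote configuration."""
    n = n_hom_ref + n_het + n_hom_alt
    nr = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)

    def prob(h: int) -> float:
        rare_hom = (nr - h) // 2
        common_hom = n - h - rare_hom
        lp = (lgamma(n + 1) - lgamma(rare_hom + 1) - lgamma(h + 1)
              - lgamma(common_hom + 1) + h * log(2)
              + lgamma(nr + 1) + lgamma(2 * n - nr + 1) - lgamma(2 * n + 1))
        return exp(lp)

    probs = {h: prob(h) for h in range(nr % 2, min(nr, 2 * n - nr) + 1, 2)}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def naive_grm(dosage: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """O(n^2 M) standardized relationship matrix by explicit double loop."""
    n, m = dosage.shape
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            acc = 0.0
            for l in range(m):
                p = freqs[l]
                acc += ((dosage[j, l] - 2 * p) * (dosage[k, l] - 2 * p)
                        / (2 * p * (1 - p)))
            out[j, k] = acc / m
    return out


def build_count_cohort(n_cases=1271, n_controls=1456, male_cases=322,
                       male_controls=400, n_resolved=308, n_stage_i_iii=433,
                       n_stage_iv=190):
    """A cohort whose phenotype table realizes exact clinical-table counts.

    Genotype/ancestry content is irrelevant for summaries; one constant
    marker is attached.
    """
    import pandas as pd

    from admixfine.cohort import SAMPLE_COLUMNS, AdmixedCohort

    n = n_cases + n_controls
    status = np.r_[np.ones(n_cases, int), np.zeros(n_controls, int)]
    sex = np.full(n, 2)
    sex[:male_cases] = 1
    sex[n_cases:n_cases + male_controls] = 1
    sub = np.full(n, "", dtype=object)
    sub[:n_resolved] = "resolved"
    sub[n_resolved:n_resolved + n_stage_i_iii] = "stage_I_III"
    sub[n_resolved + n_stage_i_iii:n_resolved + n_stage_i_iii + n_stage_iv] = "stage_IV"
    samples = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "family_id": [f"f{i}" for i in range(n)],
        "father_id": "0", "mother_id": "0",
        "sex": sex, "status": status, "subphenotype": sub,
        "theta": np.full(n, 0.82),
    })[SAMPLE_COLUMNS]
    markers = pd.DataFrame({"marker_id": ["m0"], "chrom": ["1"], "pos": [100],
                            "ref": ["A"], "alt": ["T"]})
    return AdmixedCohort(samples=samples, genotypes=np.ones((n, 1)),
                         local_ancestry=np.ones((n, 1), dtype=np.int8),
                         markers=markers)


def scenario_cohort(g, a, theta, status, rng):
    """Wrap single-marker scenario arrays as a one-marker unrelated cohort."""
    import pandas as pd

    from admixfine.cohort import SAMPLE_COLUMNS, AdmixedCohort

    n = len(status)
    samples = pd.DataFrame({
        "id": [f"s{i:05d}" for i in range(n)],
        "family_id": [f"f{i:05d}" for i in range(n)],
        "father_id": "0", "mother_id": "0",
        "sex": rng.integers(1, 3, n), "status": np.asarray(status, int),
        "subphenotype": "", "theta": np.asarray(theta, float),
    })[SAMPLE_COLUMNS]
    markers = pd.DataFrame({"marker_id": ["m0"], "chrom": ["1"], "pos": [1000],
                            "ref": ["A"], "alt": ["T"]})
    return AdmixedCohort(samples=samples,
                         genotypes=np.asarray(g, float).reshape(n, 1),
                         local_ancestry=np.asarray(a).reshape(n, 1),
                         markers=markers)


def sandwich_by_hand(X: np.ndarray, y: np.ndarray, mu: np.ndarray,
                     clusters: np.ndarray) -> np.ndarray:
    """Cluster-robust sandwich covariance for a logistic fit at mean vector mu.

    bread = (X' W X)^-1 with W = diag(mu (1-mu)); meat sums per-cluster
    outer products of the score X' (y - mu).
    """
    w = mu * (1 - mu)
    bread = np.linalg.inv(X.T @ (X * w[:, None]))
    meat = np.zeros((X.shape[1], X.shape[1]))
    for c in np.unique(clusters):
        rows = clusters == c
        s = X[rows].T @ (y[rows] - mu[rows])
        meat += np.outer(s, s)
    return bread @ meat @ bread
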