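"""Relatedness: pedigree kinship, KING-robust genotype kinship, unrelated subsets.

The coefficient of relationship between two individuals is twice the kinship
coefficient phi; first cousins have relationship 0.125, which is the
exclusion threshold used when a "nominally unrelated" subset is required for
retrospective-likelihood scores and variance-component fits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Pedigree:
    """Pedigree records; founders have father/mother id "0"."""

    records: pd.DataFrame  #: columns id, father_id, mother_id, family_id, sex

    @classmethod
    def from_samples(cls, samples: pd.DataFrame) -> "Pedigree":
        return cls(samples[["id", "father_id", "mother_id", "family_id", "sex"]].copy())

    @classmethod
    def from_ped_file(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["family_id", "id", "father_id", "mother_id", "sex", "pheno"],
                         dtype=str)
        df["sex"] = df["sex"].astype(int)
        return cls(df[["id", "father_id", "mother_id", "family_id", "sex"]])


def pedigree_kinship(ped: Pedigree) -> pd.DataFrame:
    """Kinship coefficients phi from the pedigree (no inbreeding among founders).

    Recursive definition: phi(i, i) = 0.5 * (1 + phi(f_i, m_i)),
    phi(i, j) = 0.5 * (phi(f_i, j) + phi(m_i, j)) for i not an ancestor of j.
    Raises on pedigree cycles.
    """
    df = ped.records
    ids = list(df["id"].astype(str))
    parents = {str(r["id"]): (str(r["father_id"]), str(r["mother_id"]))
               for _, r in df.iterrows()}

    depth: dict[str, int] = {}

    def _depth(i: str, stack: frozenset = frozenset()) -> int:
        if i == "0" or i not in parents:
            return 0
        if i in depth:
            return depth[i]
        if i in stack:
            raise ValueError(f"pedigree cycle involving individual {i}")
        f, m = parents[i]
        d = 1 + max(_depth(f, stack | {i}), _depth(m, stack | {i}))
        depth[i] = d
        return d

    for i in ids:
        _depth(i)

    cache: dict[tuple[str, str], float] = {}

    def phi(a: str, b: str) -> float:
        if a == "0" or b == "0":
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in cache:
            return cache[key]
        if a == b:
            f, m = parents.get(a, ("0", "0"))
            val = 0.5 * (1.0 + phi(f, m))
        else:
            # recurse through the individual deeper in the pedigree
            if depth.get(a, 0) < depth.get(b, 0):
                a, b = b, a
            f, m = parents.get(a, ("0", "0"))
            val = 0.5 * (phi(f, b) + phi(m, b)) if (f, m) != ("0", "0") else 0.0
        cache[key] = val
        return val

    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = phi(ids[i], ids[j])
    return pd.DataFrame(out, index=ids, columns=ids)


def pedigree_relationship(ped: Pedigree) -> pd.DataFrame:
    """Coefficient of relationship (2 * phi) with unit diagonal semantics.

    Diagonal is 2 * self-kinship = 1 for outbred individuals.
    """
    return 2.0 * pedigree_kinship(ped)


def king_kinship(genotypes: np.ndarray, sample_ids=None,
                 min_markers: int = 100) -> pd.DataFrame:
    """KING-robust pairwise kinship from identity-by-state counts.

    phi_ij = (N_het,het - 2 * N_opposite_hom) / (N_het,i + N_het,j), counted
    over markers non-missing in both individuals.  Robust to population
    structure because no allele frequencies enter.  Self-kinship is 0.5 by
    construction.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotypes must be (n, M)")
    n, m = g.shape
    if m < min_markers:
        import warnings
        warnings.warn(f"only {m} markers; KING kinship is noisy below {min_markers}",
                      stacklevel=2)
    valid = ~np.isnan(g)
    if not valid.any(axis=1).all():
        bad = int(np.flatnonzero(~valid.any(axis=1))[0])
        raise ValueError(f"individual {bad} has no non-missing genotypes")
    het = (g == 1) & valid
    hom0 = (g == 0) & valid
    hom2 = (g == 2) & valid
    hetf = het.astype(float)
    n_hh = hetf @ hetf.T
    n_opp = hom0.astype(float) @ hom2.astype(float).T
    n_opp = n_opp + n_opp.T
    validf = valid.astype(float)
    het_i_shared = hetf @ validf.T          # i's het markers also typed in j
    denom = het_i_shared + het_i_shared.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, (n_hh - 2.0 * n_opp) / denom, 0.0)
    np.fill_diagonal(phi, 0.5)
    ids = [str(s) for s in sample_ids] if sample_ids is not None else list(range(n))
    return pd.DataFrame(phi, index=ids, columns=ids)


def unrelated_subset(relationship: pd.DataFrame | np.ndarray,
                     threshold: float = 0.125) -> list:
    """Greedy unrelated-subset selection.

    Repeatedly removes the individual with the most relationships at or
    above ``threshold`` (ties broken by dropping the larger id) until no pair
    at or above the threshold remains; strictly-less-than-threshold pairs are
    retained.
    """
    if isinstance(relationship, pd.DataFrame):
        ids = [str(i) for i in relationship.index]
        rel = relationship.to_numpy(dtype=float)
    else:
        rel = np.asarray(relationship, dtype=float)
        ids = [str(i) for i in range(rel.shape[0])]
    if rel.ndim != 2 or rel.shape[0] != rel.shape[1]:
        raise ValueError("relationship matrix must be square")
    adj = rel >= threshold
    np.fill_diagonal(adj, False)
    active = np.ones(rel.shape[0], dtype=bool)
    while True:
        degree = (adj & active[None, :] & active[:, None]).sum(axis=1)
        degree[~active] = 0
        if degree.max(initial=0) == 0:
            break
        worst = int(max(np.flatnonzero(degree == degree.max()), key=lambda j: ids[j]))
        active[worst] = False
    return [ids[j] for j in np.flatnonzero(active)]
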