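"""Core containers and on-disk formats for two-way admixed case-control cohorts.

The in-memory model is deliberately small: a sample table (one row per
individual, with pedigree links, sex, case status, radiographic subphenotype
and global African-ancestry proportion theta), a genotype matrix of
risk-allele counts, a diploid local-ancestry matrix of African-allele counts,
and a marker map.  On disk the same cohort is a VCF (genotypes), a
local-ancestry TSV, a phenotype TSV and a 6-column linkage PED file, so that
each piece can also be supplied independently from external tools.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

#: subphenotype labels used throughout (cases with two-year follow-up only)
SUBPHENOTYPES = ("resolved", "stage_I_III", "stage_IV")
#: label for cases lacking follow-up and for controls
NO_SUBPHENOTYPE = ""

SAMPLE_COLUMNS = [
    "id", "family_id", "father_id", "mother_id",
    "sex", "status", "subphenotype", "theta",
]
MARKER_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt"]


@dataclass
class AncestralFrequencies:
    """Per-marker risk-allele frequencies on African- and European-origin haplotypes.

    A zero frequency on one background is allowed: such alleles exist only on
    haplotypes of the other ancestral origin.
    """

    f_afr: np.ndarray
    f_ceu: np.ndarray
    risk_allele: list[str] | None = None

    def __post_init__(self) -> None:
        self.f_afr = np.asarray(self.f_afr, dtype=float)
        self.f_ceu = np.asarray(self.f_ceu, dtype=float)
        if self.f_afr.shape != self.f_ceu.shape:
            raise ValueError("f_afr and f_ceu must have the same length")
        for name, f in (("f_afr", self.f_afr), ("f_ceu", self.f_ceu)):
            if np.any((f < 0) | (f > 1)):
                raise ValueError(f"{name} outside [0, 1]")

    @property
    def n_markers(self) -> int:
        return self.f_afr.shape[0]

    @classmethod
    def constant(cls, n_markers: int, f_afr: float, f_ceu: float) -> "AncestralFrequencies":
        return cls(np.full(n_markers, f_afr), np.full(n_markers, f_ceu))

    @classmethod
    def random(cls, n_markers: int, rng: np.random.Generator,
               low: float = 0.05, high: float = 0.95) -> "AncestralFrequencies":
        return cls(rng.uniform(low, high, n_markers), rng.uniform(low, high, n_markers))

    @classmethod
    def from_table(cls, path: str | os.PathLike) -> "AncestralFrequencies":
        df = pd.read_csv(path, sep="\t")
        return cls(df["f_AFR"].to_numpy(), df["f_CEU"].to_numpy(),
                   list(df["risk_allele"]) if "risk_allele" in df else None)


@dataclass
class AdmixedCohort:
    """An admixed study sample: genotypes, local ancestry, phenotypes, pedigree.

    Attributes
    ----------
    samples : DataFrame with columns id, family_id, father_id, mother_id,
        sex (1=male, 2=female), status (0/1), subphenotype, theta.
    genotypes : (n, M) float array of risk-allele counts 0/1/2, NaN = missing.
    local_ancestry : (n, M) int array of African-allele counts 0/1/2.
    markers : DataFrame with columns marker_id, chrom, pos (1-based), ref, alt.
    """

    samples: pd.DataFrame
    genotypes: np.ndarray
    local_ancestry: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        n, m = len(self.samples), len(self.markers)
        self.genotypes = np.asarray(self.genotypes, dtype=float).reshape(n, m)
        self.local_ancestry = np.asarray(self.local_ancestry).reshape(n, m).astype(np.int8)
        la = self.local_ancestry
        if la.size and (la.min() < 0 or la.max() > 2):
            raise ValueError("local ancestry counts must be in {0, 1, 2}")
        g = self.genotypes
        obs = g[~np.isnan(g)]
        if obs.size and ((obs < 0).any() or (obs > 2).any()):
            raise ValueError("genotype counts must be in {0, 1, 2} or NaN")

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def status(self) -> np.ndarray:
        return self.samples["status"].to_numpy(dtype=int)

    @property
    def theta(self) -> np.ndarray:
        return self.samples["theta"].to_numpy(dtype=float)

    @property
    def sex(self) -> np.ndarray:
        return self.samples["sex"].to_numpy(dtype=int)

    @property
    def family(self) -> np.ndarray:
        return self.samples["family_id"].to_numpy()

    def marker_index(self, marker_id: str) -> int:
        idx = self.markers.index[self.markers["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"marker {marker_id!r} not in cohort")
        return int(idx[0])

    def subset(self, row_mask: np.ndarray) -> "AdmixedCohort":
        row_mask = np.asarray(row_mask)
        if row_mask.dtype == bool:
            rows = np.flatnonzero(row_mask)
        else:
            rows = row_mask
        return AdmixedCohort(
            samples=self.samples.iloc[rows].reset_index(drop=True),
            genotypes=self.genotypes[rows],
            local_ancestry=self.local_ancestry[rows],
            markers=self.markers.copy(),
        )

    def equals(self, other: "AdmixedCohort") -> bool:
        a, b = self.genotypes, other.genotypes
        geno_eq = (a.shape == b.shape
                   and np.array_equal(np.isnan(a), np.isnan(b))
                   and np.array_equal(a[~np.isnan(a)], b[~np.isnan(b)]))
        return (
            geno_eq
            and np.array_equal(self.local_ancestry, other.local_ancestry)
            and self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
            and self.markers.reset_index(drop=True).equals(other.markers.reset_index(drop=True))
        )


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

_GT_BY_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(cohort: AdmixedCohort, path: str | os.PathLike) -> None:
    """Write genotypes as VCF v4.2 with GT only; ALT is the risk allele."""
    header = pysam.VariantHeader()
    for chrom in pd.unique(cohort.markers["chrom"]):
        sub = cohort.markers[cohort.markers["chrom"] == chrom]
        length = int(sub["pos"].max()) + 1 if len(sub) else 1
        header.contigs.add(str(chrom), length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    ids = [str(s) for s in cohort.samples["id"]]
    for s in ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for m, row in cohort.markers.iterrows():
            rec = vf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])), id=str(row["marker_id"]),
            )
            col = cohort.genotypes[:, m]
            for j, s in enumerate(ids):
                v = col[j]
                rec.samples[s]["GT"] = (None, None) if np.isnan(v) else _GT_BY_DOSAGE[int(v)]
            vf.write(rec)


def read_vcf(path: str | os.PathLike) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a GT-only VCF back into (marker map, dosage matrix, sample ids)."""
    with pysam.VariantFile(str(path)) as vf:
        ids = list(vf.header.samples)
        rows, dosages = [], []
        for rec in vf:
            rows.append({
                "marker_id": rec.id, "chrom": rec.contig, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alts[0] if rec.alts else ".",
            })
            col = np.full(len(ids), np.nan)
            for j, s in enumerate(ids):
                gt = rec.samples[s]["GT"]
                if gt is not None and None not in gt:
                    col[j] = sum(gt)
            dosages.append(col)
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    geno = np.array(dosages).T if dosages else np.empty((len(ids), 0))
    return markers, geno, ids


def write_cohort(cohort: AdmixedCohort, directory: str | os.PathLike) -> dict[str, Path]:
    """Write the four cohort files; returns the mapping of part name to path."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"cannot create cohort directory {d}: {exc}") from exc
    paths = {
        "vcf": d / "genotypes.vcf",
        "local_ancestry": d / "local_ancestry.tsv",
        "phenotypes": d / "phenotypes.tsv",
        "ped": d / "pedigree.ped",
    }
    write_vcf(cohort, paths["vcf"])

    la = pd.DataFrame(cohort.local_ancestry.T,
                      columns=[str(s) for s in cohort.samples["id"]])
    la.insert(0, "marker_id", cohort.markers["marker_id"].to_numpy())
    la.to_csv(paths["local_ancestry"], sep="\t", index=False)

    pheno = cohort.samples[["id", "family_id", "sex", "status", "subphenotype", "theta"]].copy()
    pheno["subphenotype"] = pheno["subphenotype"].fillna(NO_SUBPHENOTYPE)
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.17g")

    ped = cohort.samples[["family_id", "id", "father_id", "mother_id", "sex", "status"]].copy()
    ped["status"] = ped["status"] + 1  # linkage coding: 1 unaffected, 2 affected
    ped.to_csv(paths["ped"], sep="\t", index=False, header=False)
    return paths


def read_cohort(directory: str | os.PathLike) -> AdmixedCohort:
    d = Path(directory)
    for part in ("genotypes.vcf", "local_ancestry.tsv", "phenotypes.tsv", "pedigree.ped"):
        if not (d / part).exists():
            raise FileNotFoundError(f"missing cohort file: {d / part}")
    markers, geno, ids = read_vcf(d / "genotypes.vcf")

    la_df = pd.read_csv(d / "local_ancestry.tsv", sep="\t", dtype={"marker_id": str})
    la = la_df[ids].to_numpy().T if len(la_df) else np.empty((len(ids), 0), dtype=np.int8)

    pheno = pd.read_csv(d / "phenotypes.tsv", sep="\t", dtype={"id": str, "family_id": str},
                        float_precision="round_trip")
    pheno["subphenotype"] = pheno["subphenotype"].fillna(NO_SUBPHENOTYPE)
    ped = pd.read_csv(d / "pedigree.ped", sep="\t", header=None,
                      names=["family_id", "id", "father_id", "mother_id", "sex", "status_ped"],
                      dtype={"id": str, "family_id": str, "father_id": str, "mother_id": str})
    samples = pheno.merge(ped[["id", "father_id", "mother_id"]], on="id", how="left")
    samples = samples[SAMPLE_COLUMNS]
    samples = samples.set_index("id").loc[ids].reset_index()
    return AdmixedCohort(samples=samples, genotypes=geno, local_ancestry=la, markers=markers)
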