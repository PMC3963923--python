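"""Cohort summaries and end-to-end pipeline orchestration.

`cohort_summary` reproduces the arithmetic conventions of a clinical
characteristics table: percentages rounded half-away-from-zero at one
decimal, sex percentages against the status stratum, resolved/persistent
against cases with two-year follow-up, Scadding stage percentages against
persistent cases, and global ancestry reported as mean (SD) x 100.

`run_pipeline` chains the stages: QC -> ADM scan and region boundaries ->
GEE association with and without local-ancestry adjustment -> confounding
ratios and tiered screen -> MIX/DIFF scores -> forward selection ->
ancestry heritability with region removal -> summary, writing TSV/JSON
outputs plus a manifest.  Deterministic under a fixed seed.
"""
from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import SUBPHENOTYPES, AdmixedCohort, read_cohort, write_cohort
from . import admixscore, assoc, gqc, kin, vc


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded half-away-from-zero, as printed in summary tables."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator in summary percentage")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(numerator) * 100 / Decimal(denominator))
                 .quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Counts, printed-style percentages and ancestry moments by case status."""

    n_total: int
    n_cases: int
    n_controls: int
    male_cases: int
    male_cases_pct: float
    male_controls: int
    male_controls_pct: float
    ancestry_cases_mean: float
    ancestry_cases_sd: float
    ancestry_controls_mean: float
    ancestry_controls_sd: float
    n_followup: int
    missing_followup: int
    missing_followup_pct: float
    n_resolved: int
    resolved_pct: float
    n_persistent: int
    persistent_pct: float
    n_stage_i_iii: int
    stage_i_iii_pct: float
    n_stage_iv: int
    stage_iv_pct: float


def cohort_summary(cohort: AdmixedCohort) -> CohortSummary:
    s = cohort.samples
    cases = s[s["status"] == 1]
    controls = s[s["status"] == 0]
    if len(cases) == 0:
        raise ValueError("cohort has no cases to summarize")
    sub = cases["subphenotype"]
    n_res = int((sub == "resolved").sum())
    n_i_iii = int((sub == "stage_I_III").sum())
    n_iv = int((sub == "stage_IV").sum())
    n_persistent = n_i_iii + n_iv
    n_followup = n_res + n_persistent
    n_missing = len(cases) - n_followup

    def _pct(n, d):
        return percent(n, d) if d else float("nan")

    return CohortSummary(
        n_total=len(s), n_cases=len(cases), n_controls=len(controls),
        male_cases=int((cases["sex"] == 1).sum()),
        male_cases_pct=_pct(int((cases["sex"] == 1).sum()), len(cases)),
        male_controls=int((controls["sex"] == 1).sum()),
        male_controls_pct=_pct(int((controls["sex"] == 1).sum()), len(controls))
        if len(controls) else float("nan"),
        ancestry_cases_mean=float(np.round(100 * cases["theta"].mean(), 1)),
        ancestry_cases_sd=float(np.round(100 * cases["theta"].std(ddof=1), 1))
        if len(cases) > 1 else float("nan"),
        ancestry_controls_mean=float(np.round(100 * controls["theta"].mean(), 1))
        if len(controls) else float("nan"),
        ancestry_controls_sd=float(np.round(100 * controls["theta"].std(ddof=1), 1))
        if len(controls) > 1 else float("nan"),
        n_followup=n_followup, missing_followup=n_missing,
        missing_followup_pct=_pct(n_missing, len(cases)),
        n_resolved=n_res, resolved_pct=_pct(n_res, n_followup),
        n_persistent=n_persistent, persistent_pct=_pct(n_persistent, n_followup),
        n_stage_i_iii=n_i_iii, stage_i_iii_pct=_pct(n_i_iii, n_persistent),
        n_stage_iv=n_iv, stage_iv_pct=_pct(n_iv, n_persistent),
    )


@dataclass
class PipelineConfig:
    """End-to-end run configuration (YAML-serializable)."""

    cohort_dir: str | None = None      #: load an existing cohort; else simulate
    sim: dict = field(default_factory=dict)
    out_dir: str = "admixfine_out"
    seed: int = 0
    alpha_region: float = 0.05
    screen_p: float = 0.05
    confounding_threshold: float = 0.15
    n_subsamples: int = 0              #: 0 = score the full unrelated set once
    subsample_cases: int = 933
    subsample_controls: int = 846
    prevalence: float = 0.001
    forward_alpha: float = 0.05
    run_qc: bool = True
    heritability_source: str = "ancestry"


def _stage(manifest: dict, name: str, path: Path | None = None, **info) -> None:
    manifest["stages"].append({"stage": name,
                               "output": str(path) if path else None, **info})


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis chain; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "seed": config.seed, "stages": [],
        "versions": {"admixfine": __version__, "python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
    }

    if config.cohort_dir is not None:
        cdir = Path(config.cohort_dir)
        if not cdir.exists():
            raise FileNotFoundError(f"cohort directory not found: {cdir}")
        cohort = read_cohort(cdir)
        _stage(manifest, "load_cohort", cdir, n=cohort.n_individuals)
    else:
        from .simcohort import SimConfig, simulate_cohort
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        cohort = simulate_cohort(sim_cfg)
        paths = write_cohort(cohort, out / "cohort")
        _stage(manifest, "simulate_cohort", paths["vcf"].parent,
               n=cohort.n_individuals, markers=cohort.n_markers)

    if config.run_qc:
        mq = gqc.marker_qc(cohort.genotypes, cohort.status,
                           marker_ids=list(cohort.markers["marker_id"]))
        mq.table.to_csv(out / "marker_qc.tsv", sep="\t", index=False)
        _stage(manifest, "marker_qc", out / "marker_qc.tsv",
               n_pass=mq.n_pass, n_fail=len(mq.table) - mq.n_pass)
        keep = mq.table["pass"].to_numpy()
        if keep.any():
            cohort = AdmixedCohort(cohort.samples, cohort.genotypes[:, keep],
                                   cohort.local_ancestry[:, keep],
                                   cohort.markers[keep].reset_index(drop=True))

    # affected-only admixture scan and region boundaries
    rel = kin.pedigree_relationship(kin.Pedigree.from_samples(cohort.samples))
    adm_rows = []
    for m in range(cohort.n_markers):
        try:
            stat, p, lam = admixscore.adm_score(
                cohort.local_ancestry[cohort.status == 1, m],
                cohort.theta[cohort.status == 1])
        except ValueError:
            stat, p, lam = float("nan"), float("nan"), float("nan")
        adm_rows.append({"marker_id": cohort.markers["marker_id"][m],
                         "pos": int(cohort.markers["pos"][m]),
                         "adm_stat": stat, "adm_p": p, "lambda": lam})
    adm_df = pd.DataFrame(adm_rows)
    adm_df.to_csv(out / "adm_scan.tsv", sep="\t", index=False)
    region = admixscore.region_boundaries(adm_df["pos"].to_numpy(),
                                          adm_df["adm_p"].to_numpy(),
                                          config.alpha_region)
    _stage(manifest, "adm_scan", out / "adm_scan.tsv",
           region=list(region) if region else None)

    # GEE association with and without local-ancestry adjustment
    rows = []
    for m in range(cohort.n_markers):
        try:
            un = assoc.snp_association(cohort, m, adjust_local_ancestry=False)
            ad = assoc.snp_association(cohort, m, adjust_local_ancestry=True)
            cr = (assoc.confounding_ratio(ad.beta, un.beta)
                  if un.beta != 0 else float("nan"))
        except ValueError:
            continue
        rows.append({
            "marker_id": un.marker_id, "allele": un.coded_allele,
            "f_case": un.f_case, "f_control": un.f_control,
            "OR": un.odds_ratio, "CI_low": un.ci_low, "CI_high": un.ci_high,
            "P": un.p_value, "OR_la_adj": ad.odds_ratio, "P_la_adj": ad.p_value,
            "confounding": cr,
        })
    assoc_df = pd.DataFrame(rows)
    assoc_df.to_csv(out / "association.tsv", sep="\t", index=False)
    _stage(manifest, "association", out / "association.tsv", n_markers=len(assoc_df))

    # tiered screen and MIX/DIFF
    screened = admixscore.tiered_screen(
        dict(zip(assoc_df["marker_id"], assoc_df["P"])),
        dict(zip(assoc_df["marker_id"], assoc_df["confounding"])),
        config.screen_p, config.confounding_threshold)
    mix_rows = []
    for marker in screened:
        try:
            if config.n_subsamples > 0:
                s = admixscore.averaged_mix(
                    cohort, marker, config.n_subsamples,
                    (config.subsample_cases, config.subsample_controls),
                    rng, relationship=rel)
            else:
                s = admixscore.cohort_scores(cohort, marker)
        except ValueError:
            continue
        row = asdict(s)
        row["tier"] = s.tier()
        mix_rows.append(row)
    mix_df = pd.DataFrame(mix_rows)
    mix_df.to_csv(out / "mix_scores.tsv", sep="\t", index=False)
    _stage(manifest, "mix_scores", out / "mix_scores.tsv",
           n_screened=len(screened))

    # forward selection within the admixture region
    selected_ids: list[str] = []
    if region is not None and len(assoc_df):
        pos = cohort.markers.set_index("marker_id")["pos"]
        in_region = [m for m in assoc_df["marker_id"]
                     if region[0] <= pos[m] <= region[1]]
        if in_region:
            sel = assoc.forward_select(cohort, in_region, config.forward_alpha)
            selected_ids = [m for m, _ in sel]
            pd.DataFrame([
                {"step": i + 1, "marker_id": m, "OR": r.odds_ratio,
                 "CI_low": r.ci_low, "CI_high": r.ci_high, "P": r.p_value}
                for i, (m, r) in enumerate(sel)
            ]).to_csv(out / "forward_selection.tsv", sep="\t", index=False)
    _stage(manifest, "forward_selection", out / "forward_selection.tsv",
           selected=selected_ids)

    # heritability on the unrelated subset, with region removal
    unrel = set(kin.unrelated_subset(rel))
    sub = cohort.subset(cohort.samples["id"].astype(str).isin(unrel).to_numpy())
    h2_rows = []
    try:
        full, dropped = vc.drop_region_heritability(
            sub, config.heritability_source, region, config.prevalence)
        h2_rows.append({"analysis": "all_markers", **asdict(full)})
        if region is not None:
            h2_rows.append({"analysis": "admixture_region_removed", **asdict(dropped)})
    except (ValueError, RuntimeError) as exc:
        _stage(manifest, "heritability_failed", error=str(exc))
    if h2_rows:
        pd.DataFrame(h2_rows).to_csv(out / "heritability.tsv", sep="\t", index=False)
        _stage(manifest, "heritability", out / "heritability.tsv",
               h2_obs=h2_rows[0]["h2_obs"], h2_liab=h2_rows[0]["h2_liab"])

    summary = cohort_summary(cohort)
    (out / "summary.json").write_text(json.dumps(asdict(summary), indent=2))
    _stage(manifest, "summary", out / "summary.json")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
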