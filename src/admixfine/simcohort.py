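"""Synthetic two-way admixed cohort generator.

Emulates the statistical structure an admixture fine-mapping analysis of an
African-American case-control sample relies on: individual global African
ancestry theta drawn from a Beta distribution moment-matched to a target mean
and SD; block-wise local ancestry along a chromosome from a two-state Markov
chain whose switch rate reflects the number of generations since the
admixture pulse (one expected crossover per Morgan per generation, with a
constant 1e-8 per-bp recombination rate mapping position to genetic
distance); genotypes drawn per haplotype from ancestry-specific allele
frequencies (alleles absent from one ancestral population are allowed);
sibships built from two simulated parents through meiosis so that family
clusters carry realistic genotype and ancestry sharing; and a multiplicative
(log-additive) logistic disease model with global-ancestry and sex effects,
optional per-locus causal alleles and an optional direct local-ancestry
effect, plus radiographic subphenotypes assigned among cases.

Alleles are independent across markers given ancestry (no background LD), so
every locus-level statistic has a known truth to recover.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import (
    MARKER_COLUMNS,
    NO_SUBPHENOTYPE,
    SAMPLE_COLUMNS,
    SUBPHENOTYPES,
    AdmixedCohort,
    AncestralFrequencies,
)
from .cohort import write_cohort  # re-exported for convenience  # noqa: F401

#: constant recombination rate used to map bp to Morgans
MORGANS_PER_BP = 1e-8


@dataclass
class DiseaseModel:
    """Multiplicative logistic disease model.

    logit P(case) = intercept + sum_m log_or[m] * g_m + gamma * theta
                    + delta * 1{male} + ancestry_log_or * a_locus
    """

    intercept: float = float(logit(1271 / 2727))
    causal: dict[int, float] = field(default_factory=dict)  #: marker index -> allelic log OR
    gamma: float = 0.0            #: log-odds per unit global African ancestry
    delta: float = 0.0            #: log-odds for male sex
    ancestry_effect: float = 0.0  #: log-odds per African allele at ancestry_locus
    ancestry_locus: int | None = None

    def __post_init__(self) -> None:
        vals = [self.intercept, self.gamma, self.delta, self.ancestry_effect,
                *self.causal.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("disease model parameters must be finite")


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults follow the admixed sarcoidosis study design this package
    emulates: mean African ancestry 0.82 (SD 0.10), seven generations since
    admixture, roughly 47% cases, subphenotypes (resolved, persistent Stage
    I-III, Stage IV) in proportions (0.331, 0.465, 0.204) among cases with
    follow-up, and 26.8% of cases missing follow-up.
    """

    n_individuals: int = 400          #: unrelated singletons
    n_families: int = 50              #: families of 2 parents + sibship_size sibs
    sibship_size: int = 2
    n_markers: int = 200
    chrom_length: int = 50_000_000    #: bp
    generations_since_admixture: float = 7.0
    theta_mean: float = 0.82
    theta_sd: float = 0.10
    freq_table: AncestralFrequencies | None = None
    disease: DiseaseModel = field(default_factory=DiseaseModel)
    subphenotype_probs: tuple[float, float, float] = (0.331, 0.465, 0.204)
    followup_missing_rate: float = 0.268
    missing_rate: float = 0.0         #: uniform genotype missingness
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta_mean < 1:
            raise ValueError("theta_mean must lie strictly in (0, 1)")
        if self.theta_sd <= 0:
            raise ValueError("theta_sd must be positive")
        if self.n_markers < 1:
            raise ValueError("need at least one marker")
        p = np.asarray(self.subphenotype_probs, dtype=float)
        if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
            raise ValueError("subphenotype_probs must be 3 non-negative values summing to 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    def beta_params(self) -> tuple[float, float]:
        """Moment-matched Beta(alpha, beta) for the theta distribution."""
        m, v = self.theta_mean, self.theta_sd ** 2
        nu = m * (1 - m) / v - 1
        if nu <= 0:
            raise ValueError(
                f"theta_sd={self.theta_sd} too large for mean {self.theta_mean}: "
                "no Beta distribution has these moments")
        return m * nu, (1 - m) * nu


def simulate_marker_scenario(n_cases: int, n_controls: int, p_afr: float, p_eur: float,
                             rng: np.random.Generator, allelic_or: float = 1.0,
                             theta_mean: float = 0.82, theta_sd: float = 0.10,
                             prevalence: float = 0.02,
                             ancestry_or: float = 1.0):
    """Retrospectively sampled single-marker case-control data.

    Individuals are drawn from an admixed population (theta ~ Beta matched to
    (theta_mean, theta_sd); diploid local ancestry Binomial(2, theta);
    genotype per haplotype Bernoulli(p_afr / p_eur)) and become cases with
    probability expit(logit(prevalence) + g*log(allelic_or) +
    a*log(ancestry_or)); sampling continues until the requested numbers of
    cases and controls are collected.  Returns (genotype, ancestry, theta,
    status) arrays of length n_cases + n_controls, cases first.

    With allelic_or = ancestry_or = 1 the marker is null; with allelic_or
    != 1 and ancestry_or = 1 it is the single causal variant of an induced
    admixture signal.
    """
    cfg = SimConfig(n_individuals=1, n_markers=1,
                    theta_mean=theta_mean, theta_sd=theta_sd)
    alpha, beta = cfg.beta_params()
    need = {1: n_cases, 0: n_controls}
    got: dict[int, list[np.ndarray]] = {0: [], 1: []}
    base = logit(prevalence)
    while need[0] > 0 or need[1] > 0:
        batch = max(2000, int(4 * max(need[1] / prevalence, need[0])))
        batch = min(batch, 500_000)
        th = rng.beta(alpha, beta, batch)
        a = rng.binomial(2, th)
        g = rng.binomial(a, p_afr) + rng.binomial(2 - a, p_eur)
        lp = base + g * np.log(allelic_or) + a * np.log(ancestry_or)
        y = (rng.random(batch) < expit(lp)).astype(int)
        for s in (1, 0):
            if need[s] > 0:
                rows = np.flatnonzero(y == s)[: need[s]]
                got[s].append(np.column_stack([g[rows], a[rows], th[rows]]))
                need[s] -= rows.size
    stacked = np.vstack(got[1] + got[0])
    status = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    return (stacked[:, 0].astype(int), stacked[:, 1].astype(int),
            stacked[:, 2], status)


def simulate_local_ancestry(theta: float, marker_positions: np.ndarray,
                            generations: float, rng: np.random.Generator) -> np.ndarray:
    """Simulate one haplotype's ancestry (1 = African, 0 = European) per marker.

    Two-state Markov chain with stationary distribution (theta, 1 - theta)
    and per-interval refresh probability 1 - exp(-g * d) for inter-marker
    distance d in Morgans, i.e. a Markov approximation of a g-generation
    admixture pulse.  The marginal P(African) is theta at every marker.
    """
    pos = np.asarray(marker_positions, dtype=float)
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    if pos.ndim != 1 or pos.size == 0:
        raise ValueError("marker_positions must be a non-empty 1-d array")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("marker positions must be strictly increasing")
    m = pos.size
    out = np.empty(m, dtype=np.int8)
    d = np.diff(pos) * MORGANS_PER_BP
    refresh = 1.0 - np.exp(-generations * d)
    out[0] = rng.random() < theta
    u_refresh = rng.random(m - 1)
    u_state = rng.random(m - 1)
    for i in range(1, m):
        if u_refresh[i - 1] < refresh[i - 1]:
            out[i] = u_state[i - 1] < theta
        else:
            out[i] = out[i - 1]
    return out


def _haplotype_alleles(anc: np.ndarray, freqs: AncestralFrequencies,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw one haplotype's risk alleles given its per-marker ancestry."""
    p = np.where(anc == 1, freqs.f_afr, freqs.f_ceu)
    return (rng.random(anc.size) < p).astype(np.int8)


def _meiosis(hap_a: tuple[np.ndarray, np.ndarray], hap_b: tuple[np.ndarray, np.ndarray],
             positions: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Recombine a parent's two haplotypes into one gamete.

    Crossovers follow a Haldane (no-interference) model: the transmitted
    parental strand switches between markers with probability
    0.5 * (1 - exp(-2d)) for inter-marker distance d Morgans.
    """
    m = positions.size
    d = np.diff(positions) * MORGANS_PER_BP
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    strand = np.empty(m, dtype=np.int8)
    strand[0] = rng.random() < 0.5
    switches = rng.random(m - 1) < r
    strand[1:] = (strand[0] + np.cumsum(switches)) % 2
    anc = np.where(strand == 0, hap_a[0], hap_b[0])
    alleles = np.where(strand == 0, hap_a[1], hap_b[1])
    return anc.astype(np.int8), alleles.astype(np.int8)


def _simulate_founder(theta: float, positions: np.ndarray, freqs: AncestralFrequencies,
                      generations: float, rng: np.random.Generator):
    haps = []
    for _ in range(2):
        anc = simulate_local_ancestry(theta, positions, generations, rng)
        haps.append((anc, _haplotype_alleles(anc, freqs, rng)))
    return haps


def simulate_cohort(config: SimConfig) -> AdmixedCohort:
    """Generate a cohort of unrelated singletons plus nuclear families.

    Families contribute both parents and ``sibship_size`` children; the
    children's haplotypes are meiotic recombinations of the parental ones, so
    sibs share genotype, ancestry and family id.  Phenotypes are assigned by
    :func:`assign_phenotypes` using ``config.disease``.
    """
    rng = np.random.default_rng(config.seed)
    alpha, beta = config.beta_params()
    freqs = config.freq_table
    if freqs is None:
        freqs = AncestralFrequencies.random(config.n_markers, rng)
    if freqs.n_markers != config.n_markers:
        raise ValueError("freq_table length does not match n_markers")

    positions = np.sort(rng.choice(
        np.arange(1, config.chrom_length + 1), size=config.n_markers, replace=False))
    markers = pd.DataFrame({
        "marker_id": [f"rs{i:06d}" for i in range(config.n_markers)],
        "chrom": config.chrom, "pos": positions, "ref": "A", "alt": "T",
    }, columns=MARKER_COLUMNS)

    records, la_rows, g_rows = [], [], []

    def add_individual(iid, fid, father, mother, theta, haps):
        sex = 1 if rng.random() < 0.5 else 2
        la_rows.append(haps[0][0] + haps[1][0])
        g_rows.append(haps[0][1] + haps[1][1])
        records.append({"id": iid, "family_id": fid, "father_id": father,
                        "mother_id": mother, "sex": sex, "status": 0,
                        "subphenotype": NO_SUBPHENOTYPE, "theta": theta})

    for i in range(config.n_individuals):
        theta = float(rng.beta(alpha, beta))
        haps = _simulate_founder(theta, positions, freqs,
                                 config.generations_since_admixture, rng)
        add_individual(f"I{i:05d}", f"S{i:05d}", "0", "0", theta, haps)

    for f in range(config.n_families):
        fid = f"F{f:04d}"
        parent_haps, parent_thetas, parent_ids = [], [], []
        for p in range(2):
            theta = float(rng.beta(alpha, beta))
            haps = _simulate_founder(theta, positions, freqs,
                                     config.generations_since_admixture, rng)
            pid = f"{fid}P{p}"
            add_individual(pid, fid, "0", "0", theta, haps)
            records[-1]["sex"] = 1 if p == 0 else 2  # one father, one mother
            parent_haps.append(haps)
            parent_thetas.append(theta)
            parent_ids.append(pid)
        for c in range(config.sibship_size):
            gametes = [_meiosis(parent_haps[p][0], parent_haps[p][1], positions, rng)
                       for p in range(2)]
            mid_theta = 0.5 * (parent_thetas[0] + parent_thetas[1])
            add_individual(f"{fid}C{c}", fid, parent_ids[0], parent_ids[1],
                           mid_theta, gametes)

    samples = pd.DataFrame(records, columns=SAMPLE_COLUMNS)
    genotypes = np.array(g_rows, dtype=float)
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = np.nan
    cohort = AdmixedCohort(samples=samples, genotypes=genotypes,
                           local_ancestry=np.array(la_rows), markers=markers)
    return assign_phenotypes(cohort, config.disease, rng,
                             subphenotype_probs=config.subphenotype_probs,
                             followup_missing_rate=config.followup_missing_rate)


def assign_phenotypes(cohort: AdmixedCohort, model: DiseaseModel,
                      rng: np.random.Generator,
                      subphenotype_probs: tuple[float, float, float] = (0.331, 0.465, 0.204),
                      followup_missing_rate: float = 0.268) -> AdmixedCohort:
    """Draw case status from the logistic model and subphenotypes among cases.

    Individuals with a missing genotype at a causal marker contribute that
    term as its ancestry-conditional expectation, keeping the linear
    predictor finite.
    """
    n = cohort.n_individuals
    lp = np.full(n, model.intercept, dtype=float)
    for m_idx, log_or in model.causal.items():
        if not 0 <= m_idx < cohort.n_markers:
            raise KeyError(f"causal marker index {m_idx} not in cohort")
        g = cohort.genotypes[:, m_idx]
        g = np.where(np.isnan(g), 2 * cohort.theta, g)
        lp += log_or * g
    lp += model.gamma * cohort.theta
    lp += model.delta * (cohort.sex == 1)
    if model.ancestry_effect != 0.0:
        if model.ancestry_locus is None:
            raise ValueError("ancestry_effect set but ancestry_locus is None")
        lp += model.ancestry_effect * cohort.local_ancestry[:, model.ancestry_locus]
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")

    status = (rng.random(n) < expit(lp)).astype(int)
    sub = np.full(n, NO_SUBPHENOTYPE, dtype=object)
    cases = np.flatnonzero(status == 1)
    has_followup = rng.random(cases.size) >= followup_missing_rate
    labels = rng.choice(len(SUBPHENOTYPES), size=cases.size, p=subphenotype_probs)
    for k, j in enumerate(cases):
        if has_followup[k]:
            sub[j] = SUBPHENOTYPES[labels[k]]

    samples = cohort.samples.copy()
    samples["status"] = status
    samples["subphenotype"] = sub
    return AdmixedCohort(samples=samples, genotypes=cohort.genotypes,
                         local_ancestry=cohort.local_ancestry, markers=cohort.markers)
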