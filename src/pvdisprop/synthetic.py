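"""Seeded synthetic spontaneous-report databases with planted signals.

Real pharmacovigilance databases (VigiBase, FAERS) are access-restricted,
so the analysis pipeline is exercised on synthetic databases that emulate
their statistical structure: tens of thousands of multi-drug reports with
suspect/interacting/concomitant roles, a target Preferred Term at low
marginal frequency, drug-specific reporting associations of known strength,
demographics, seriousness, outcomes, and entry dates spanning years with an
optional late surge for a vaccine group.

Generative model, per report:

1. Number of drugs ~ geometric (mean ``drugs_per_report_mean``) truncated
   to [1, ``drugs_per_report_max``]; distinct drugs drawn without
   replacement with probability proportional to their catalog weight
   (Gumbel top-k). When catalog weights sum to the mean drugs-per-report,
   each weight is approximately the drug's realized per-report inclusion
   probability.
2. Each mention is concomitant with probability ``concomitant_fraction``,
   otherwise interacting with probability ``interacting_fraction`` and
   suspect with the remainder. Only suspect/interacting mentions carry
   planted effects, matching the exposure definition used downstream.
3. Each PT is a Bernoulli draw at its baseline probability times the
   largest planted rate ratio λ among the report's exposed drugs (capped at
   1; max, not product, keeps probabilities bounded). Reports are
   conditioned on having at least one reaction — a spontaneous report
   without any ADR does not exist — implemented as exact sequential
   conditional sampling, distributionally identical to redrawing empty
   reports.
4. Demographics, reporter qualification, and entry year come from the
   demographic profile of the report's group (first matching group label
   among its exposed drugs, else the default profile); outcome, seriousness
   and country are global categoricals. Ages are normal, truncated to
   [0, 110].

Everything is driven by one ``numpy`` Generator, so a fixed config and seed
reproduce the database byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .data_model import EXPOSURE_ROLES, ReportDatabase
from .errors import ConfigError

AGE_TRUNCATION = (0.0, 110.0)


@dataclass(frozen=True)
class DrugSpec:
    drug_id: str
    name: str
    weight: float  # target per-report inclusion probability (see module doc)
    atc_codes: tuple = ()
    group_labels: tuple = ()


@dataclass(frozen=True)
class PtSpec:
    pt: str
    baseline: float  # per-report reaction probability under no exposure


@dataclass(frozen=True)
class PlantedEffect:
    drug_id: str
    pt: str
    rate_ratio: float  # λ: multiplies the PT baseline for exposed reports


@dataclass
class DemographicProfile:
    """Sex / age / reporter / entry-year profile for one report group."""

    female_frac: float = 0.64
    sex_unknown_frac: float = 0.04
    age_mean: float = 50.0
    age_sd: float = 16.0
    age_missing_frac: float = 0.15
    reporter_probs: dict = field(default_factory=lambda: {
        "physician": 0.25, "pharmacist": 0.07,
        "other_health_professional": 0.09, "lawyer": 0.002,
        "consumer": 0.40, "unknown": 0.188})
    year_weights: dict = field(default_factory=lambda: {2020: 0.5,
                                                        2021: 0.5})


@dataclass
class SyntheticConfig:
    """Generative parameters for one synthetic report database."""

    n_reports: int
    seed: int
    drugs: list
    pts: list
    planted_effects: list = field(default_factory=list)
    drugs_per_report_mean: float = 1.8
    drugs_per_report_max: int = 10
    concomitant_fraction: float = 0.25
    interacting_fraction: float = 0.05
    demographics: dict = field(default_factory=dict)
    outcome_probs: dict = field(default_factory=lambda: {
        "recovered": 0.161, "recovering": 0.049, "not_recovered": 0.256,
        "recovered_with_sequelae": 0.015, "fatal": 0.004, "unknown": 0.515})
    serious_probs: dict = field(default_factory=lambda: {
        "yes": 0.229, "no": 0.55, "unknown": 0.221})
    country_probs: dict = field(default_factory=lambda: {
        "US": 0.533, "DE": 0.096, "GB": 0.086, "NL": 0.046, "FR": 0.025,
        "other": 0.214})
    tto_log_mean: float = math.log(11.0)
    tto_log_sd: float = 2.2
    tto_missing_frac: float = 0.5

    def __post_init__(self):
        self.drugs = [d if isinstance(d, DrugSpec) else DrugSpec(**d)
                      for d in self.drugs]
        self.pts = [p if isinstance(p, PtSpec) else PtSpec(**p)
                    for p in self.pts]
        self.planted_effects = [
            e if isinstance(e, PlantedEffect) else PlantedEffect(**e)
            for e in self.planted_effects]
        self.demographics = {
            k: (v if isinstance(v, DemographicProfile)
                else DemographicProfile(**v))
            for k, v in self.demographics.items()}
        self.demographics.setdefault("default", DemographicProfile())

    def validate(self):
        if self.n_reports < 1:
            raise ConfigError("n_reports must be positive")
        if not self.drugs or not self.pts:
            raise ConfigError("drug and PT catalogs must be non-empty")
        if len({d.drug_id for d in self.drugs}) != len(self.drugs):
            raise ConfigError("duplicate drug_id in catalog")
        for d in self.drugs:
            if d.weight < 0:
                raise ConfigError(f"negative weight for {d.drug_id}")
        baselines = {p.pt: p.baseline for p in self.pts}
        for p in self.pts:
            if not 0.0 <= p.baseline <= 1.0:
                raise ConfigError(f"baseline for {p.pt} outside [0, 1]")
        if sum(baselines.values()) <= 0:
            raise ConfigError("at least one PT needs a positive baseline")
        known_drugs = {d.drug_id for d in self.drugs}
        for e in self.planted_effects:
            if e.rate_ratio < 0:
                raise ConfigError(
                    f"negative rate ratio for ({e.drug_id}, {e.pt})")
            if e.drug_id not in known_drugs or e.pt not in baselines:
                raise ConfigError(
                    f"planted effect references unknown pair "
                    f"({e.drug_id}, {e.pt})")
            if e.rate_ratio * baselines[e.pt] > 1.0:
                raise ConfigError(
                    f"probability overflow: rate ratio {e.rate_ratio} x "
                    f"baseline {baselines[e.pt]} > 1 for "
                    f"({e.drug_id}, {e.pt})")
        for frac in (self.concomitant_fraction, self.interacting_fraction,
                     self.tto_missing_frac):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        for name, prof in self.demographics.items():
            if abs(sum(prof.year_weights.values()) - 1.0) > 1e-6:
                raise ConfigError(
                    f"year_weights for profile '{name}' must sum to 1")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What was actually planted and realized — enables recovery tests."""

    planted: dict  # (drug_id, pt) -> rate ratio λ
    exposure_counts: dict  # drug_id -> distinct exposed-report count
    case_counts: dict  # (drug_id, pt) -> exposed reports listing the PT


def _categorical(rng: np.random.Generator, probs: dict, n: int) -> np.ndarray:
    keys = sorted(probs, key=str)
    p = np.array([probs[k] for k in keys], dtype=float)
    total = p.sum()
    if total <= 0:
        raise ConfigError("categorical distribution has no mass")
    cum = np.cumsum(p / total)
    idx = np.searchsorted(cum, rng.random(n), side="right")
    return np.array(keys, dtype=object)[np.minimum(idx, len(keys) - 1)]


def _truncated_normal(rng, mean, sd, lo, hi, n):
    # inverse-CDF on the shared Generator keeps determinism in one stream
    alo, ahi = norm.cdf((lo - mean) / sd), norm.cdf((hi - mean) / sd)
    return mean + sd * norm.ppf(alo + rng.random(n) * (ahi - alo))


def _conditional_reactions(rng, p: np.ndarray) -> np.ndarray:
    """Bernoulli matrix conditioned on >=1 success per row (exact).

    Sequential chain-rule sampling: at column j, rows still without a
    success draw with probability p_j / (1 − Π_{l≥j}(1 − p_l)), which is
    the conditional law given that a success must still occur.
    """
    n, m = p.shape
    tail_none = np.ones((n, m + 1))  # tail_none[:, j] = Π_{l>=j}(1-p_l)
    tail_none[:, :-1] = np.cumprod((1.0 - p)[:, ::-1], axis=1)[:, ::-1]
    x = np.zeros((n, m), dtype=bool)
    has_success = np.zeros(n, dtype=bool)
    for j in range(m):
        u = rng.random(n)
        p_cond = p[:, j].copy()
        need = ~has_success
        denom = 1.0 - tail_none[:, j]
        safe = denom > 0
        p_cond[need & safe] = (p[need & safe, j] / denom[need & safe])
        x[:, j] = u < p_cond
        has_success |= x[:, j]
    return x


def generate(config: SyntheticConfig) -> tuple[ReportDatabase, GroundTruth]:
    """Draw one synthetic database; deterministic given the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = config.drugs
    n_drugs = len(drugs)
    pts = config.pts

    # number of drugs per report: truncated geometric
    k = rng.geometric(1.0 / config.drugs_per_report_mean, size=n)
    k = np.minimum(k, min(config.drugs_per_report_max, n_drugs))

    # weighted distinct drugs per report via Gumbel top-k
    w = np.array([d.weight for d in drugs], dtype=float)
    if w.sum() <= 0:
        raise ConfigError("drug weights must have positive total mass")
    logw = np.log(np.where(w > 0, w, 1e-300))
    keys = logw[None, :] + rng.gumbel(size=(n, n_drugs))
    # continuous keys are tie-free, so default introsort is deterministic
    order = np.argsort(-keys, axis=1)
    take = np.arange(n_drugs)[None, :] < k[:, None]
    mention_report = np.repeat(np.arange(n), k)
    mention_drug = order[take]

    # roles
    u = rng.random(len(mention_drug))
    conc = config.concomitant_fraction
    inter = conc + (1.0 - conc) * config.interacting_fraction
    role = np.full(len(mention_drug), "suspect", dtype=object)
    role[u < inter] = "interacting"
    role[u < conc] = "concomitant"
    exposed_mention = role != "concomitant"

    # per-report exposure flags per drug (suspect/interacting only)
    exposed_matrix = np.zeros((n, n_drugs), dtype=bool)
    exposed_matrix[mention_report[exposed_mention],
                   mention_drug[exposed_mention]] = True

    # reaction probabilities: baseline x max planted λ over exposed drugs
    # (drugs with no planted effect carry λ = 1, so a report mixing planted
    # and unplanted exposures never drops below baseline)
    drug_index = {d.drug_id: i for i, d in enumerate(drugs)}
    pt_index = {p.pt: j for j, p in enumerate(pts)}
    prob = np.tile(np.array([p.baseline for p in pts]), (n, 1))
    planted_by_pt: dict[int, list] = {}
    for eff in config.planted_effects:
        planted_by_pt.setdefault(pt_index[eff.pt], []).append(
            (drug_index[eff.drug_id], eff.rate_ratio))
    exposed_any = exposed_matrix.any(axis=1)
    for pj, entries in planted_by_pt.items():
        lam_planted = np.zeros(n)
        for di, lam_v in entries:
            rows = exposed_matrix[:, di]
            lam_planted[rows] = np.maximum(lam_planted[rows], lam_v)
        planted_cols = {di for di, _ in entries}
        unplanted = [i for i in range(n_drugs) if i not in planted_cols]
        other = (exposed_matrix[:, unplanted].any(axis=1) if unplanted
                 else np.zeros(n, dtype=bool))
        lam = np.where(other, np.maximum(lam_planted, 1.0), lam_planted)
        lam[~exposed_any] = 1.0
        prob[:, pj] = np.minimum(pts[pj].baseline * lam, 1.0)
    reactions = _conditional_reactions(rng, prob)

    # demographic group: first matching group label among exposed drugs
    group_names = sorted(g for g in config.demographics if g != "default")
    group_of_report = np.full(n, "default", dtype=object)
    for g in reversed(group_names):  # earlier names take priority
        members = [i for i, d in enumerate(drugs) if g in d.group_labels]
        if members:
            hit = exposed_matrix[:, members].any(axis=1)
            group_of_report[hit] = g

    sex = np.empty(n, dtype=object)
    age = np.full(n, np.nan)
    reporter = np.empty(n, dtype=object)
    year = np.empty(n, dtype=int)
    for g in ["default"] + group_names:
        prof = config.demographics[g]
        mask = group_of_report == g
        m = int(mask.sum())
        u_sex = rng.random(m)
        s = np.where(u_sex < prof.sex_unknown_frac, "unknown",
                     np.where(u_sex < prof.sex_unknown_frac
                              + (1 - prof.sex_unknown_frac)
                              * prof.female_frac, "female", "male"))
        sex[mask] = s
        ages = _truncated_normal(rng, prof.age_mean, prof.age_sd,
                                 *AGE_TRUNCATION, m)
        ages[rng.random(m) < prof.age_missing_frac] = np.nan
        age[mask] = np.round(ages, 1)
        reporter[mask] = _categorical(rng, prof.reporter_probs, m)
        year[mask] = _categorical(rng, prof.year_weights, m).astype(int)

    outcome = _categorical(rng, config.outcome_probs, n)
    serious = _categorical(rng, config.serious_probs, n)
    country = _categorical(rng, config.country_probs, n)
    day = rng.integers(0, 365, size=n)
    jan1 = pd.to_datetime(pd.Series(year).astype(str), format="%Y")
    entry_date = ((jan1 + pd.to_timedelta(day, unit="D"))
                  .dt.strftime("%Y-%m-%d").to_numpy())

    tto = np.round(rng.lognormal(config.tto_log_mean, config.tto_log_sd,
                                 size=len(mention_drug)), 1)
    tto[rng.random(len(mention_drug)) < config.tto_missing_frac] = np.nan

    width = len(str(n - 1))
    report_ids = np.array([f"R{i:0{width}d}" for i in range(n)],
                          dtype=object)
    drug_ids = np.array([d.drug_id for d in drugs], dtype=object)

    reports = pd.DataFrame({
        "report_id": report_ids, "entry_date": entry_date,
        "country": country, "reporter_qualification": reporter,
        "serious": serious, "sex": sex, "age_years": age,
        "outcome": outcome})
    drug_mentions = pd.DataFrame({
        "report_id": report_ids[mention_report],
        "drug_id": drug_ids[mention_drug], "role": role,
        "time_to_onset_days": tto})
    rep_idx, pt_idx = np.nonzero(reactions)
    reaction_mentions = pd.DataFrame({
        "report_id": report_ids[rep_idx],
        "pt": np.array([p.pt for p in pts], dtype=object)[pt_idx]})
    drug_dictionary = pd.DataFrame({
        "drug_id": drug_ids, "name": [d.name for d in drugs],
        "atc_codes": [list(d.atc_codes) for d in drugs],
        "group_labels": [list(d.group_labels) for d in drugs]})
    db = ReportDatabase(reports, drug_mentions, reaction_mentions,
                        drug_dictionary)

    exposure_counts = {
        d.drug_id: int(exposed_matrix[:, i].sum())
        for i, d in enumerate(drugs)}
    case_counts = {}
    for eff in config.planted_effects:
        di, pj = drug_index[eff.drug_id], pt_index[eff.pt]
        case_counts[(eff.drug_id, eff.pt)] = int(
            (exposed_matrix[:, di] & reactions[:, pj]).sum())
    truth = GroundTruth(
        planted={(e.drug_id, e.pt): e.rate_ratio
                 for e in config.planted_effects},
        exposure_counts=exposure_counts, case_counts=case_counts)
    return db, truth


def default_parosmia_scenario(n_reports: int = 100_000, seed: int = 0
                              ) -> SyntheticConfig:
    """A documented scenario shaped like a smell-disorder signal study.

    ~45 drugs including a 4-member "COVID-19 vaccine" group with a late
    reporting surge, the target PT "Parosmia" at a ≈5e-4 baseline, an
    overall female preponderance, and planted reporting rate ratios
    spanning 1–150 (the strongest for an inhaled-corticosteroid analogue).
    Catalog weights sum to the mean drugs-per-report, so each weight is
    approximately that drug's per-report inclusion probability.
    """
    vax = ("COVID-19 vaccine",)
    drugs = [
        # fillers with no planted effect
        DrugSpec("paracetamol", "Paracetamol", 0.20, ("N02BE01",)),
        DrugSpec("ibuprofen", "Ibuprofen", 0.15, ("M01AE01",)),
        DrugSpec("amoxicillin", "Amoxicillin", 0.10, ("J01CA04",)),
        DrugSpec("metformin", "Metformin", 0.10, ("A10BA02",)),
        DrugSpec("atorvastatin", "Atorvastatin", 0.10, ("C10AA05",)),
        DrugSpec("omeprazole", "Omeprazole", 0.10, ("A02BC01",)),
        DrugSpec("lisinopril", "Lisinopril", 0.08, ("C09AA03",)),
        DrugSpec("levothyroxine", "Levothyroxine", 0.08, ("H03AA01",)),
        DrugSpec("sertraline", "Sertraline", 0.05, ("N06AB06",)),
        DrugSpec("aspirin", "Acetylsalicylic acid", 0.10, ("B01AC06",)),
        DrugSpec("amlodipine", "Amlodipine", 0.12, ("C08CA01",)),
        DrugSpec("simvastatin", "Simvastatin", 0.10, ("C10AA01",)),
        DrugSpec("influenza_vaccine", "Influenza vaccine", 0.03,
                 ("J07BB02",)),
        # COVID-19 vaccine group
        DrugSpec("tozinameran", "Tozinameran", 0.10, ("J07BN01",), vax),
        DrugSpec("elasomeran", "Elasomeran", 0.04, ("J07BN02",), vax),
        DrugSpec("azd1222", "AZD1222", 0.04, ("J07BN03",), vax),
        DrugSpec("jnj_78436735", "JNJ-78436735", 0.01, ("J07BN04",), vax),
        # corticosteroids (nasal/inhaled)
        DrugSpec("flunisolide", "Flunisolide", 0.004, ("R01AD04",)),
        DrugSpec("beclometasone", "Beclometasone", 0.0025, ("R03BA01",)),
        DrugSpec("mometasone", "Mometasone", 0.003, ("R01AD09",)),
        DrugSpec("fluticasone", "Fluticasone", 0.008, ("R01AD08",)),
        DrugSpec("budesonide", "Budesonide", 0.005, ("R03BA02",)),
        DrugSpec("triamcinolone", "Triamcinolone", 0.004, ("R01AD11",)),
        # antibiotics
        DrugSpec("clarithromycin", "Clarithromycin", 0.010, ("J01FA09",)),
        DrugSpec("roxithromycin", "Roxithromycin", 0.0025, ("J01FA06",)),
        DrugSpec("azithromycin", "Azithromycin", 0.015, ("J01FA10",)),
        DrugSpec("ciprofloxacin", "Ciprofloxacin", 0.025, ("J01MA02",)),
        DrugSpec("ofloxacin", "Ofloxacin", 0.005, ("J01MA01",)),
        DrugSpec("moxifloxacin", "Moxifloxacin", 0.009, ("J01MA14",)),
        DrugSpec("doxycycline", "Doxycycline", 0.008, ("J01AA02",)),
        DrugSpec("metronidazole", "Metronidazole", 0.014, ("J01XD01",)),
        # nicotine dependence
        DrugSpec("varenicline", "Varenicline", 0.017, ("N07BA03",)),
        DrugSpec("bupropion", "Bupropion", 0.014, ("N06AX12",)),
        DrugSpec("nicotine", "Nicotine", 0.014, ("N07BA01",)),
        # antidepressants
        DrugSpec("duloxetine", "Duloxetine", 0.013, ("N06AX21",)),
        DrugSpec("paroxetine", "Paroxetine", 0.014, ("N06AB05",)),
        DrugSpec("venlafaxine", "Venlafaxine", 0.013, ("N06AX16",)),
        DrugSpec("citalopram", "Citalopram", 0.008, ("N06AB04",)),
        # incretin mimetics
        DrugSpec("exenatide", "Exenatide", 0.014, ("A10BJ01",)),
        DrugSpec("dulaglutide", "Dulaglutide", 0.010, ("A10BJ05",)),
        DrugSpec("liraglutide", "Liraglutide", 0.008, ("A10BJ02",)),
        # others with known smell-disorder associations
        DrugSpec("oxymetazoline", "Oxymetazoline", 0.001, ("R01AA05",)),
        DrugSpec("hpv_vaccine", "HPV vaccine", 0.020, ("J07BM01",)),
        DrugSpec("terbinafine", "Terbinafine", 0.005, ("D01BA02",)),
        DrugSpec("salbutamol", "Salbutamol", 0.015, ("R03AC02",)),
        DrugSpec("teriparatide", "Teriparatide", 0.030, ("H05AA02",)),
        DrugSpec("ipratropium", "Ipratropium", 0.0018, ("R01AX03",)),
        DrugSpec("ribavirin", "Ribavirin", 0.020, ("J05AP01",)),
    ]
    pts = [
        PtSpec("Parosmia", 5e-4), PtSpec("Hyposmia", 6e-5),
        PtSpec("Anosmia", 3e-4), PtSpec("Dysgeusia", 0.02),
        PtSpec("Nausea", 0.30), PtSpec("Headache", 0.30),
        PtSpec("Dizziness", 0.25), PtSpec("Fatigue", 0.25),
        PtSpec("Rash", 0.20), PtSpec("Pyrexia", 0.20),
        PtSpec("Vomiting", 0.15), PtSpec("Diarrhoea", 0.15),
        PtSpec("Pruritus", 0.10), PtSpec("Insomnia", 0.10),
        PtSpec("Myalgia", 0.15), PtSpec("Arthralgia", 0.10),
        PtSpec("Drug ineffective", 0.25),
    ]
    par = {
        "flunisolide": 150.0, "oxymetazoline": 41.0, "beclometasone": 26.0,
        "ipratropium": 25.0, "roxithromycin": 20.0, "mometasone": 14.0,
        "fluticasone": 12.0, "clarithromycin": 11.7, "terbinafine": 9.3,
        "ofloxacin": 7.4, "varenicline": 5.8, "azithromycin": 4.3,
        "doxycycline": 4.3, "moxifloxacin": 4.1, "triamcinolone": 3.9,
        "budesonide": 3.7, "tozinameran": 3.3, "jnj_78436735": 3.2,
        "elasomeran": 2.8, "azd1222": 2.3, "ribavirin": 2.5,
        "duloxetine": 2.5, "bupropion": 2.4, "ciprofloxacin": 2.0,
        "salbutamol": 2.0, "exenatide": 2.0, "hpv_vaccine": 2.0,
        "paroxetine": 1.9, "dulaglutide": 1.7, "metronidazole": 1.7,
        "liraglutide": 1.6, "citalopram": 1.6, "nicotine": 1.5,
        "venlafaxine": 1.5, "teriparatide": 1.3,
    }
    hypo = {"oxymetazoline": 250.0, "fluticasone": 60.0,
            "tozinameran": 3.3, "elasomeran": 2.8, "azd1222": 2.3,
            "jnj_78436735": 3.2}
    effects = ([PlantedEffect(d, "Parosmia", lam) for d, lam in par.items()]
               + [PlantedEffect(d, "Hyposmia", lam)
                  for d, lam in hypo.items()])

    other_years = {y: 1.0 for y in range(2002, 2022)}
    total = sum(other_years.values())
    other_years = {y: v / total for y, v in other_years.items()}
    demographics = {
        "default": DemographicProfile(
            female_frac=0.653, age_mean=47.1, age_sd=15.5,
            year_weights=other_years),
        "COVID-19 vaccine": DemographicProfile(
            female_frac=0.715, age_mean=53.2, age_sd=16.3,
            reporter_probs={"physician": 0.06, "pharmacist": 0.02,
                            "other_health_professional": 0.05,
                            "lawyer": 0.001, "consumer": 0.58,
                            "unknown": 0.289},
            year_weights={2020: 0.05, 2021: 0.95}),
    }
    return SyntheticConfig(n_reports=n_reports, seed=seed, drugs=drugs,
                           pts=pts, planted_effects=effects,
                           demographics=demographics)
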