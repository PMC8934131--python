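"""Internally consistent synthetic input bundles.

Real inputs for this kind of model (national survey exposure, burden-of-
disease epidemiology, expenditure tables) are not redistributable, so every
pipeline stage is exercised against generated data: a smooth population
pyramid with Gompertz all-cause mortality, unimodal disease incidence with
prevalence derived *through the illness-death engine* (never drawn
independently — consistency holds by construction), Dirichlet-style
exposure proportions around survey-like centres, and per-study effects for
meta-analysis recovery experiments.  Everything is a deterministic function
of the seed.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .disease_model import (
    DiseaseDefinition,
    DiseaseEpi,
    SexEpi,
    default_disease_definitions,
    solve_illness_death,
)
from .errors import DomainError
from .evidence import RRTable, StudyEffect, fixture_rr_table, Z975
from .exposure import (
    AGE_BANDS,
    CATEGORIES,
    CATEGORY_BOUNDS,
    SEXES,
    ExposureStratum,
    ExposureTable,
)
from .lifetable import CostInputs, PopulationTable
from .scenarios import ModelInputs

#: Per-disease synthetic epidemiology shapes: (peak age, peak incidence/yr,
#: case fatality/yr, disability weight, cost per case A$).
DEFAULT_DISEASE_PARAMS = {
    "type2_diabetes": {"peak_age": 65, "peak_rate": 0.008, "case_fatality": 0.012,
                       "disability_weight": 0.07, "cost_per_case": 2200.0},
    "stroke": {"peak_age": 80, "peak_rate": 0.006, "case_fatality": 0.06,
               "disability_weight": 0.18, "cost_per_case": 9000.0},
    "breast_cancer": {"peak_age": 62, "peak_rate": 0.0035, "case_fatality": 0.03,
                      "disability_weight": 0.10, "cost_per_case": 12000.0},
    "colorectal_cancer": {"peak_age": 72, "peak_rate": 0.0025, "case_fatality": 0.05,
                          "disability_weight": 0.10, "cost_per_case": 28000.0},
    "endometrial_cancer": {"peak_age": 64, "peak_rate": 0.0012, "case_fatality": 0.025,
                           "disability_weight": 0.09, "cost_per_case": 24000.0},
}

_EXPOSURE_CENTRES = (0.30, 0.36, 0.34)
_MEAN_RANGES = {"low": (150.0, 220.0), "moderate": (300.0, 420.0), "high": (520.0, 700.0)}


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    start_age: int = 18
    end_age: int = 100
    total_population: float = 1.0e7
    gompertz_a: float = 4.0e-5
    gompertz_b: float = 0.095
    base_yld_rate: float = 0.05
    exposure_dirichlet_concentration: float = 200.0
    disease_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_DISEASE_PARAMS.items()
    })
    study_k: int = 6
    true_log_rr: float = 0.27
    tau: float = 0.10

    def __post_init__(self) -> None:
        if self.end_age <= self.start_age:
            raise DomainError("end_age must exceed start_age")
        if self.gompertz_a < 0 or self.gompertz_b < 0:
            raise DomainError("Gompertz parameters must be >= 0")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.end_age + 1)


def _rng(cfg: SynthConfig, *stream: str) -> np.random.Generator:
    # one independent, reproducible stream per generated artefact
    # (crc32, not hash(): stable across processes)
    key = tuple(zlib.crc32(s.encode()) for s in stream)
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=key))


def generate_population(cfg: SynthConfig) -> PopulationTable:
    """Smooth population pyramid with Gompertz all-cause mortality."""
    ages = cfg.ages
    pyramid = np.exp(-0.5 * ((ages - 40.0) / 28.0) ** 2)
    mortality = np.minimum(cfg.gompertz_a * np.exp(cfg.gompertz_b * ages), 1.0)
    yld = np.clip(cfg.base_yld_rate + 0.10 * (ages / 100.0) ** 2, 0.0, 1.0)
    pop, mort, w = {}, {}, {}
    for k, sex in enumerate(SEXES):
        share = pyramid / pyramid.sum() * (cfg.total_population / len(SEXES))
        pop[sex] = share
        # males carry slightly higher background mortality
        mort[sex] = np.minimum(mortality * (1.0 + 0.1 * k), 1.0)
        w[sex] = yld
    return PopulationTable(ages=ages, population=pop, mortality=mort, total_yld_rate=w)


def generate_disease_epi(cfg: SynthConfig, disease: str) -> DiseaseEpi:
    """Unimodal incidence by age; prevalence and mortality via the illness-death solve."""
    params = cfg.disease_params[disease]
    ages = cfg.ages
    incidence = params["peak_rate"] * np.exp(-0.5 * ((ages - params["peak_age"]) / 15.0) ** 2)
    case_fatality = np.full(len(ages), params["case_fatality"])
    remission = np.zeros(len(ages))
    dw = params["disability_weight"]
    sexes = ("female",) if disease in ("breast_cancer", "endometrial_cancer") else SEXES
    by_sex = {}
    for sex in sexes:
        state = solve_illness_death(
            incidence, case_fatality, remission, 0.0, cfg.start_age, cfg.end_age, p_start=0.0
        )
        by_sex[sex] = SexEpi(
            incidence=incidence,
            prevalence=state.prevalence,
            case_fatality=case_fatality,
            remission=remission,
            yld_rate=state.prevalence * dw,
        )
    return DiseaseEpi(disease=disease, disability_weight=dw, ages=ages, by_sex=by_sex)


def generate_exposure(cfg: SynthConfig) -> ExposureTable:
    """Exposure proportions around survey-like centres; means inside category bounds."""
    rng = _rng(cfg, "exposure")
    conc = cfg.exposure_dirichlet_concentration
    strata = {}
    for sex in SEXES:
        for band in AGE_BANDS:
            p = rng.dirichlet(np.asarray(_EXPOSURE_CENTRES) * conc)
            means = np.array([rng.uniform(*_MEAN_RANGES[c]) for c in CATEGORIES])
            strata[(sex, band)] = ExposureStratum(
                sex=sex,
                age_band=band,
                proportion=p,
                proportion_se=np.full(3, 0.015),
                mean_minutes=means,
                mean_se=np.array([4.0, 4.0, 12.0]),
            )
    return ExposureTable(strata)


def generate_costs(cfg: SynthConfig) -> CostInputs:
    defs = default_disease_definitions()
    costs = {}
    bases = {}
    n = len(cfg.ages)
    for defn in defs:
        per_case = cfg.disease_params[defn.name]["cost_per_case"]
        costs[defn.name] = {sex: np.full(n, per_case) for sex in defn.sexes}
        bases[defn.name] = defn.cost_basis
    return CostInputs(costs=costs, bases=bases)


def generate_study_effects(
    cfg: SynthConfig, disease: str, contrast: str, se_range: tuple[float, float] = (0.05, 0.15)
) -> list[StudyEffect]:
    """Per-study log-RRs ~ Normal(true_log_rr, tau^2) plus within-study noise."""
    if cfg.study_k < 1:
        raise DomainError("study_k must be >= 1")
    rng = _rng(cfg, "studies", disease, contrast)
    out = []
    for j in range(cfg.study_k):
        theta = rng.normal(cfg.true_log_rr, cfg.tau)
        se = rng.uniform(*se_range)
        y = rng.normal(theta, se)
        out.append(
            StudyEffect(
                study_id=f"{disease}_{contrast}_{j:02d}",
                disease=disease,
                category_contrast=contrast,
                rr=float(np.exp(y)),
                ci_low=float(np.exp(y - Z975 * se)),
                ci_high=float(np.exp(y + Z975 * se)),
            )
        )
    return out


def generate_bundle(cfg: SynthConfig, rr_table: RRTable | None = None) -> ModelInputs:
    """Full, validated model-input bundle (exposure, RRs, population, epi, costs)."""
    defs = default_disease_definitions()
    diseases = tuple((d, generate_disease_epi(cfg, d.name)) for d in defs)
    return ModelInputs(
        exposure=generate_exposure(cfg),
        rr=rr_table if rr_table is not None else fixture_rr_table(),
        population=generate_population(cfg),
        diseases=diseases,
        costs=generate_costs(cfg),
    )


def write_bundle(cfg: SynthConfig, out_dir) -> dict:
    """Write the CSV bundle plus a manifest recording seed and config."""
    from .disease_model import epi_to_frame
    from .exposure import CATEGORIES as CATS

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(cfg)

    bundle.exposure.to_frame().to_csv(out / "exposure.csv", index=False)
    bundle.rr.to_frame().to_csv(out / "rr.csv", index=False)

    pop_rows = []
    pt = bundle.population
    for sex in pt.sexes():
        for j, age in enumerate(pt.ages):
            pop_rows.append(
                {
                    "sex": sex,
                    "age": int(age),
                    "population": pt.population[sex][j],
                    "all_cause_mortality": pt.mortality[sex][j],
                    "total_yld_rate": pt.total_yld_rate[sex][j],
                }
            )
    pd.DataFrame(pop_rows).to_csv(out / "population.csv", index=False)

    epi_frames = [epi_to_frame(epi) for _, epi in bundle.diseases]
    pd.concat(epi_frames, ignore_index=True).to_csv(out / "disease_epi.csv", index=False)

    cost_rows = []
    for defn, _ in bundle.diseases:
        for sex in defn.sexes:
            cost_rows.append(
                {
                    "disease": defn.name,
                    "sex": sex,
                    "age_band": "all",
                    "cost_basis": defn.cost_basis,
                    "cost_aud": cfg.disease_params[defn.name]["cost_per_case"],
                }
            )
    pd.DataFrame(cost_rows).to_csv(out / "costs.csv", index=False)

    study_frames = []
    for defn, _ in bundle.diseases:
        for contrast in ("moderate_vs_low", "high_vs_low"):
            effects = generate_study_effects(cfg, defn.name, contrast)
            study_frames.append(
                pd.DataFrame(
                    [
                        {
                            "study_id": e.study_id,
                            "disease": e.disease,
                            "contrast": e.category_contrast,
                            "rr": e.rr,
                            "ci_low": e.ci_low,
                            "ci_high": e.ci_high,
                        }
                        for e in effects
                    ]
                )
            )
    pd.concat(study_frames, ignore_index=True).to_csv(out / "study_effects.csv", index=False)

    manifest = {
        "seed": cfg.seed,
        "config": {
            k: (v if not isinstance(v, dict) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "files": [
            "exposure.csv",
            "rr.csv",
            "population.csv",
            "disease_epi.csv",
            "costs.csv",
            "study_effects.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
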