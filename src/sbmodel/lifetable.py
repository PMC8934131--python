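"""Proportional multi-state life table: HALYs, deaths, incident cases, cost offsets.

Each disease process is solved once per sex across the age grid (the
illness-death engine), under business-as-usual incidence and under
scenario incidence i' = i * (1 - PIF).  Differences in disease mortality
and prevalent morbidity feed back into shared cohort life tables; outputs
are population-scaled differences accumulated over the analysis horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .disease_model import (
    DiseaseDefinition,
    DiseaseEpi,
    solve_illness_death,
)
from .errors import DomainError, SchemaError, ValidationError
from .exposure import AGE_BAND_RANGES, AGE_BANDS, SEXES

METRICS = ("halys_gained", "cost_offset", "deaths_averted", "cases_prevented")


@dataclass(frozen=True)
class PopulationTable:
    """Population counts, all-cause mortality and total morbidity by sex and age."""

    ages: np.ndarray
    population: Mapping[str, np.ndarray]
    mortality: Mapping[str, np.ndarray]
    total_yld_rate: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        object.__setattr__(self, "ages", ages)
        for name in ("population", "mortality", "total_yld_rate"):
            mapping = dict(getattr(self, name))
            for sex, arr in mapping.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != ages.shape:
                    raise ValidationError(f"{name}[{sex}] shape {arr.shape} != age grid")
                if np.any(arr < 0):
                    raise ValidationError(f"{name}[{sex}] contains negative values")
                mapping[sex] = arr
            object.__setattr__(self, name, mapping)
        for sex, arr in self.total_yld_rate.items():
            if np.any(arr > 1):
                raise ValidationError(f"total_yld_rate[{sex}] exceeds 1")

    def sexes(self) -> list[str]:
        return list(self.population)


@dataclass(frozen=True)
class CostInputs:
    """Per-disease healthcare cost per case by sex and age (already inflated)."""

    costs: Mapping[str, Mapping[str, np.ndarray]]  # disease -> sex -> per-age cost
    bases: Mapping[str, str]  # disease -> cost basis

    def cost_array(self, disease: str, sex: str, n_ages: int) -> np.ndarray:
        arr = self.costs.get(disease, {}).get(sex)
        if arr is None:
            return np.zeros(n_ages)
        return np.broadcast_to(np.asarray(arr, dtype=float), (n_ages,))


def empty_costs() -> CostInputs:
    return CostInputs(costs={}, bases={})


def load_costs(path, inflation_index: float = 1.0, *, ages: np.ndarray | None = None,
               definitions: Sequence[DiseaseDefinition] = ()) -> CostInputs:
    """Read the costs CSV (disease, sex, age_band, cost_basis, cost_aud).

    Costs are multiplied by ``inflation_index`` at load.  ``age_band`` may be
    one of the exposure bands or ``all``; band values are broadcast to the
    single-year age grid.
    """
    frame = pd.read_csv(path)
    required = {"disease", "sex", "age_band", "cost_basis", "cost_aud"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"costs CSV missing columns: {sorted(missing)}")
    if (frame["cost_aud"] < 0).any():
        raise ValidationError("negative cost in costs CSV")
    expected_basis = {d.name: d.cost_basis for d in definitions}
    if ages is None:
        ages = np.arange(18, 101)
    ages = np.asarray(ages, dtype=int)
    costs: dict[str, dict[str, np.ndarray]] = {}
    bases: dict[str, str] = {}
    for row in frame.itertuples():
        disease, sex, band = row.disease, row.sex, row.age_band
        basis = row.cost_basis
        if disease in expected_basis and basis != expected_basis[disease]:
            raise SchemaError(
                f"{disease}: cost basis {basis!r} does not match the disease "
                f"definition ({expected_basis[disease]!r})"
            )
        if bases.setdefault(disease, basis) != basis:
            raise SchemaError(f"{disease}: inconsistent cost bases in costs CSV")
        arr = costs.setdefault(disease, {}).setdefault(sex, np.zeros(len(ages)))
        if band == "all":
            lo, hi = int(ages[0]), int(ages[-1])
        elif band in AGE_BAND_RANGES:
            lo, hi = AGE_BAND_RANGES[band]
        else:
            raise SchemaError(f"unknown age band {band!r} in costs CSV")
        mask = (ages >= lo) & (ages <= hi)
        arr[mask] = float(row.cost_aud) * inflation_index
    return CostInputs(costs=costs, bases=bases)


@dataclass(frozen=True)
class CohortLifeTable:
    """Life-table columns for a single-age cohort followed over the horizon."""

    start_age: int
    q: np.ndarray
    l: np.ndarray  # length horizon + 1, l[0] = 1
    L: np.ndarray
    w: np.ndarray
    Lw: np.ndarray


@dataclass(frozen=True)
class LifeTableModel:
    """Validated baseline state: population, disease processes and costs."""

    population: PopulationTable
    diseases: Sequence[tuple[DiseaseDefinition, DiseaseEpi]]
    costs: CostInputs

    def __post_init__(self) -> None:
        ages = self.population.ages
        missing = []
        for defn, epi in self.diseases:
            if defn.name != epi.disease:
                raise ValidationError(f"definition/epi mismatch: {defn.name} vs {epi.disease}")
            if not np.array_equal(epi.ages, ages):
                raise ValidationError(
                    f"{defn.name}: epi age grid {epi.ages[0]}..{epi.ages[-1]} does not match "
                    f"population grid {ages[0]}..{ages[-1]}"
                )
            for sex in defn.sexes:
                if sex not in epi.by_sex:
                    missing.append((defn.name, sex))
                if sex not in self.population.population:
                    missing.append(("population", sex))
        if missing:
            raise ValidationError(f"model grid incomplete; missing cells: {missing}")

    @property
    def ages(self) -> np.ndarray:
        return self.population.ages


def build_model(
    pop: PopulationTable,
    diseases: Sequence[tuple[DiseaseDefinition, DiseaseEpi]],
    costs: CostInputs | None = None,
) -> LifeTableModel:
    return LifeTableModel(population=pop, diseases=tuple(diseases), costs=costs or empty_costs())


@dataclass
class OutputSummary:
    """HALYs gained, cost offsets, deaths averted and cases prevented.

    ``by_sex_disease`` indexes (sex, disease) rows with one column per
    metric; sex-level and grand totals are exact sums over the rows.
    """

    by_sex_disease: pd.DataFrame
    horizon_years: float = 1.0
    discount_rate: float = 0.0

    def total(self, metric: str) -> float:
        return float(self.by_sex_disease[metric].sum())

    def by_sex(self, metric: str) -> pd.Series:
        return self.by_sex_disease.groupby(level="sex")[metric].sum()

    def by_disease(self, metric: str) -> pd.Series:
        return self.by_sex_disease.groupby(level="disease")[metric].sum()

    def to_series(self) -> pd.Series:
        """Flatten to one value per (metric, sex, disease) plus totals."""
        parts = {}
        for metric in METRICS:
            parts[(metric, "total", "all")] = self.total(metric)
            for (sex, disease), value in self.by_sex_disease[metric].items():
                parts[(metric, sex, disease)] = float(value)
            for sex, value in self.by_sex(metric).items():
                parts[(metric, sex, "all")] = float(value)
        series = pd.Series(parts)
        series.index.names = ["metric", "sex", "disease"]
        return series


def pifs_by_age(
    pif_values: Mapping[tuple[str, str], float], sex: str, ages: np.ndarray
) -> np.ndarray:
    """Broadcast per-(sex, age_band) PIFs onto the single-year age grid."""
    out = np.zeros(len(ages))
    for (psex, band), value in pif_values.items():
        if psex != sex:
            continue
        if band not in AGE_BAND_RANGES:
            raise DomainError(f"unknown age band {band!r} in PIF set")
        lo, hi = AGE_BAND_RANGES[band]
        out[(ages >= lo) & (ages <= hi)] = value
    return out


def _cohort_accumulate(
    m: np.ndarray, horizon: int, discount_rate: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Survivorship bookkeeping for all single-age cohorts simultaneously.

    Returns (L_by_cohort_year, idx_by_cohort_year, l_final) where
    L_by_cohort_year[t, k] are the person-years lived in year t by cohort k
    and idx_by_cohort_year[t, k] is the age index whose rates apply (clamped
    at the last age for open-ended survival).
    """
    n = len(m)
    k = np.arange(n)
    l = np.ones(n)
    L = np.empty((horizon, n))
    idx = np.empty((horizon, n), dtype=int)
    for t in range(horizon):
        age_idx = np.minimum(k + t, n - 1)
        surv = np.exp(-m[age_idx])
        l_next = l * surv
        L[t] = 0.5 * (l + l_next)
        idx[t] = age_idx
        l = l_next
    return L, idx, l


def run_comparison(
    model: LifeTableModel,
    pif_values: Mapping[str, Mapping[tuple[str, str], float]],
    horizon_years: int = 1,
    discount_rate: float = 0.0,
) -> OutputSummary:
    """Business-as-usual vs scenario comparison.

    ``pif_values`` maps disease -> {(sex, age_band): PIF}.  For each sex the
    scenario incidence is i' = i (1 - PIF); prevalence and disease mortality
    are re-derived through the illness-death engine; total mortality and
    morbidity adjust by the summed disease differences; cohort life tables
    then yield population-scaled HALYs gained, deaths averted, incident
    cases prevented and healthcare cost offsets.  HALYs and costs are
    discounted exponentially; deaths and cases are reported undiscounted.
    """
    if horizon_years < 1:
        raise DomainError("horizon_years must be >= 1")
    known = {defn.name for defn, _ in model.diseases}
    unknown = set(pif_values) - known
    if unknown:
        raise DomainError(f"PIFs supplied for unknown diseases: {sorted(unknown)}")
    for disease, per_stratum in pif_values.items():
        defn = next(d for d, _ in model.diseases if d.name == disease)
        for (sex, band) in per_stratum:
            if sex not in defn.sexes:
                raise DomainError(f"PIF for {disease} refers to non-applicable sex {sex!r}")
            if band not in AGE_BANDS:
                raise DomainError(f"unknown age band {band!r} in PIF set for {disease}")

    ages = model.ages
    n = len(ages)
    horizon = int(horizon_years)
    disc = (1.0 + discount_rate) ** (-np.arange(horizon))

    rows = []
    for sex in model.population.sexes():
        m = model.population.mortality[sex]
        w_total = model.population.total_yld_rate[sex]
        N = model.population.population[sex]

        per_disease = []
        dm_delta = np.zeros(n)  # sum_d (m_d - m_d')
        dp_dw_delta = np.zeros(n)  # sum_d (p_d - p'_d) dw_d
        for defn, epi in model.diseases:
            if sex not in defn.sexes:
                continue
            sex_epi = epi.by_sex[sex]
            pif_age = pifs_by_age(pif_values.get(defn.name, {}), sex, ages)
            start, end = int(ages[0]), int(ages[-1])
            p0 = float(sex_epi.prevalence[0])
            bau = solve_illness_death(
                sex_epi.incidence, sex_epi.case_fatality, sex_epi.remission, m, start, end, p0
            )
            if np.all(pif_age == 0.0):
                scn = bau  # identical inputs: reuse so the null scenario is exactly zero
            else:
                scn = solve_illness_death(
                    sex_epi.incidence * (1.0 - pif_age),
                    sex_epi.case_fatality,
                    sex_epi.remission,
                    m,
                    start,
                    end,
                    p0,
                )
            dm_delta += bau.disease_mortality - scn.disease_mortality
            dp_dw_delta += (bau.prevalence - scn.prevalence) * epi.disability_weight
            per_disease.append((defn, epi, sex_epi, pif_age, bau, scn))

        m_scn = np.maximum(m - dm_delta, 0.0)
        w_bau = w_total
        w_scn = np.clip(w_total - dp_dw_delta, 0.0, 1.0)

        L_bau, idx, _ = _cohort_accumulate(m, horizon, discount_rate)
        L_scn, _, _ = _cohort_accumulate(m_scn, horizon, discount_rate)

        # Cohort-year weights: person-years lived, population-scaled.
        # idx[t, k] is shared (the clamped age index) between the arms.
        halys_sex = 0.0
        morb_parts: dict[str, float] = {}
        mort_weights: dict[str, float] = {}
        mort_weight_total = 0.0
        for t in range(horizon):
            lw_b = L_bau[t] * (1.0 - w_bau[idx[t]])
            lw_s = L_scn[t] * (1.0 - w_scn[idx[t]])
            halys_sex += float(np.sum(N * (lw_s - lw_b)) * disc[t])

        for defn, epi, sex_epi, pif_age, bau, scn in per_disease:
            name = defn.name
            cost = model.costs.cost_array(name, sex, n)
            deaths_d = 0.0
            cases_d = 0.0
            cost_d = 0.0
            morb_d = 0.0
            mw_d = 0.0
            i_bau = sex_epi.incidence
            i_scn = i_bau * (1.0 - pif_age)
            for t in range(horizon):
                a = idx[t]
                py_b, py_s = L_bau[t], L_scn[t]
                deaths_d += float(
                    np.sum(N * (py_b * bau.disease_mortality[a] - py_s * scn.disease_mortality[a]))
                )
                d_cases = np.sum(
                    N
                    * (
                        py_b * (1.0 - bau.prevalence[a]) * i_bau[a]
                        - py_s * (1.0 - scn.prevalence[a]) * i_scn[a]
                    )
                )
                cases_d += float(d_cases)
                if defn.cost_basis == "per_prevalent_case":
                    cost_d += float(
                        np.sum(N * (py_b * bau.prevalence[a] - py_s * scn.prevalence[a]) * cost[a])
                        * disc[t]
                    )
                else:  # per incident case
                    cost_d += float(
                        np.sum(
                            N
                            * (
                                py_b * (1.0 - bau.prevalence[a]) * i_bau[a]
                                - py_s * (1.0 - scn.prevalence[a]) * i_scn[a]
                            )
                            * cost[a]
                        )
                        * disc[t]
                    )
                # Exactly additive morbidity component of the HALY gain.
                morb_d += float(
                    np.sum(
                        N
                        * L_scn[t]
                        * (bau.prevalence[a] - scn.prevalence[a])
                        * epi.disability_weight
                    )
                    * disc[t]
                )
                mw_d += float(
                    np.sum(
                        N
                        * L_scn[t]
                        * (bau.disease_mortality[a] - scn.disease_mortality[a])
                    )
                    * disc[t]
                )
            morb_parts[name] = morb_d
            mort_weights[name] = mw_d
            mort_weight_total += mw_d
            rows.append(
                {
                    "sex": sex,
                    "disease": name,
                    "deaths_averted": deaths_d,
                    "cases_prevented": cases_d,
                    "cost_offset": cost_d,
                }
            )

        # Attribute the sex-level HALY gain across diseases: the morbidity
        # component is additive by construction; the survival component is
        # split in proportion to each disease's mortality-reduction weight.
        mort_part = halys_sex - sum(morb_parts.values())
        n_dis = len(per_disease)
        for row in rows[-n_dis:] if n_dis else []:
            name = row["disease"]
            if mort_weight_total != 0.0:
                share = mort_weights[name] / mort_weight_total
            else:
                share = 1.0 / n_dis if n_dis else 0.0
            row["halys_gained"] = morb_parts[name] + mort_part * share

    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(
            columns=["sex", "disease", *METRICS]
        ).astype({m: float for m in METRICS})
    frame = frame.set_index(["sex", "disease"])[list(METRICS)]
    return OutputSummary(
        by_sex_disease=frame, horizon_years=horizon_years, discount_rate=discount_rate
    )


def population_from_frame(frame: pd.DataFrame) -> PopulationTable:
    required = {"sex", "age", "population", "all_cause_mortality", "total_yld_rate"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"population CSV missing columns: {sorted(missing)}")
    ages = np.sort(frame["age"].unique())
    pop, mort, yld = {}, {}, {}
    for sex, sub in frame.groupby("sex"):
        sub = sub.sort_values("age")
        if not np.array_equal(sub["age"].to_numpy(), ages):
            raise ValidationError(f"population table: age grid differs for sex {sex!r}")
        pop[sex] = sub["population"].to_numpy(dtype=float)
        mort[sex] = sub["all_cause_mortality"].to_numpy(dtype=float)
        yld[sex] = sub["total_yld_rate"].to_numpy(dtype=float)
    return PopulationTable(ages=ages, population=pop, mortality=mort, total_yld_rate=yld)


def load_population(path) -> PopulationTable:
    return population_from_frame(pd.read_csv(path))
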