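"""Four-state generic disease engine: healthy / diseased / dead-from-disease / dead-other.

Transitions run at piecewise-constant rates per one-year age interval:
incidence i (healthy -> diseased), remission r (diseased -> healthy),
case fatality f (diseased -> dead-from-disease) and background mortality
m_other (healthy, diseased -> dead-other).  Each interval is propagated
with the exact matrix exponential of the generator, evaluated in closed
form for the 2x2 living-states block (Putzer's algorithm); occupancy-time
integrals give the exact inflow into the dead states.

Because m_other applies equally to both living states, the implied
prevalence p(a) = C / (S + C) is independent of the m_other series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, ValidationError

DISEASE_NAMES = (
    "type2_diabetes",
    "stroke",
    "breast_cancer",
    "colorectal_cancer",
    "endometrial_cancer",
)
FEMALE_ONLY = ("breast_cancer", "endometrial_cancer")
COST_BASES = ("per_incident_case", "per_prevalent_case")
#: Healthcare cost basis per disease.
DEFAULT_COST_BASIS = {
    "type2_diabetes": "per_prevalent_case",
    "stroke": "per_prevalent_case",
    "breast_cancer": "per_prevalent_case",
    "colorectal_cancer": "per_incident_case",
    "endometrial_cancer": "per_incident_case",
}


@dataclass(frozen=True)
class DiseaseDefinition:
    name: str
    sexes: tuple[str, ...]
    cost_basis: str
    remission_allowed: bool = False

    def __post_init__(self) -> None:
        if self.cost_basis not in COST_BASES:
            raise ValidationError(f"{self.name}: unknown cost basis {self.cost_basis!r}")


def default_disease_definitions() -> list[DiseaseDefinition]:
    """The five modelled diseases; breast and endometrial cancer female-only."""
    out = []
    for name in DISEASE_NAMES:
        sexes = ("female",) if name in FEMALE_ONLY else ("female", "male")
        out.append(DiseaseDefinition(name=name, sexes=sexes, cost_basis=DEFAULT_COST_BASIS[name]))
    return out


@dataclass(frozen=True)
class SexEpi:
    """Per-age rate arrays for one sex (aligned with DiseaseEpi.ages)."""

    incidence: np.ndarray
    prevalence: np.ndarray
    case_fatality: np.ndarray
    remission: np.ndarray
    yld_rate: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.incidence)
        for name in dataclasses.fields(self):
            arr = np.asarray(getattr(self, name.name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"epi field {name.name} has shape {arr.shape}, expected ({n},)")
            if np.any(arr < 0):
                raise ValidationError(f"epi field {name.name} contains negative values")
            object.__setattr__(self, name.name, arr)
        if np.any(self.prevalence >= 1):
            raise ValidationError("prevalence must be < 1")


@dataclass(frozen=True)
class DiseaseEpi:
    """Incidence / prevalence / case-fatality / remission / YLD for one disease."""

    disease: str
    disability_weight: float
    ages: np.ndarray
    by_sex: Mapping[str, SexEpi]

    def __post_init__(self) -> None:
        if not 0 <= self.disability_weight <= 1:
            raise ValidationError("disability weight must be in [0, 1]")
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=int))
        object.__setattr__(self, "by_sex", dict(self.by_sex))

    def sexes(self) -> list[str]:
        return list(self.by_sex)


@dataclass(frozen=True)
class DiseaseState:
    """State-occupancy trajectory by age: S, C, D_d, D_o plus derived p and m_d."""

    ages: np.ndarray
    S: np.ndarray
    C: np.ndarray
    D_d: np.ndarray
    D_o: np.ndarray
    prevalence: np.ndarray = field(default=None)  # type: ignore[assignment]
    disease_mortality: np.ndarray = field(default=None)  # type: ignore[assignment]

    def conservation_error(self) -> float:
        return float(np.max(np.abs(self.S + self.C + self.D_d + self.D_o - 1.0)))


def _putzer_2x2(M: np.ndarray, h: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """exp(M h) and int_0^h exp(M t) dt for a batch of 2x2 matrices.

    M has shape (n, 2, 2).  Eigenvalues are real for generator sub-blocks
    (off-diagonal entries are non-negative); near-degenerate pairs fall back
    to the analytic limit of the divided difference.
    """
    a, b = M[:, 0, 0], M[:, 0, 1]
    c, d = M[:, 1, 0], M[:, 1, 1]
    tr = a + d
    disc = (a - d) ** 2 + 4 * b * c
    sq = np.sqrt(np.maximum(disc, 0.0))
    l1 = 0.5 * (tr + sq)
    l2 = 0.5 * (tr - sq)
    dl = l1 - l2

    e1 = np.exp(l1 * h)
    e2 = np.exp(l2 * h)
    degenerate = np.abs(dl) < 1e-9
    safe_dl = np.where(degenerate, 1.0, dl)
    c1 = np.where(degenerate, h * e1, (e1 - e2) / safe_dl)

    def phi(lam, elam):
        small = np.abs(lam) < 1e-12
        return np.where(small, h, (elam - 1.0) / np.where(small, 1.0, lam))

    p1 = phi(l1, e1)
    p2 = phi(l2, e2)
    # d/dlam [(e^{lam h} - 1)/lam] for the degenerate branch
    small1 = np.abs(l1) < 1e-12
    dphi = np.where(
        small1,
        0.5 * h**2,
        (h * e1 * np.where(small1, 1.0, l1) - (e1 - 1.0)) / np.where(small1, 1.0, l1) ** 2,
    )
    c2 = np.where(degenerate, dphi, (p1 - p2) / safe_dl)

    eye = np.broadcast_to(np.eye(2), M.shape)
    shifted = M - l1[:, None, None] * eye
    expM = e1[:, None, None] * eye + c1[:, None, None] * shifted
    intM = p1[:, None, None] * eye + c2[:, None, None] * shifted
    return expM, intM


def solve_illness_death(
    incidence,
    case_fatality,
    remission,
    other_mortality,
    start_age: int,
    end_age: int,
    p_start: float = 0.0,
) -> DiseaseState:
    """Propagate the four-state model over one-year intervals.

    Rate arrays are indexed by age (length end_age - start_age + 1); the
    value at age x applies on [x, x+1).  Returns state occupancies at each
    integer age together with prevalence among the living p(a) = C/(S+C)
    and the population disease-mortality rate m_d(a) = p(a) * f(a).
    """
    ages = np.arange(start_age, end_age + 1)
    n = len(ages)
    i = np.broadcast_to(np.asarray(incidence, dtype=float), (n,))
    f = np.broadcast_to(np.asarray(case_fatality, dtype=float), (n,))
    r = np.broadcast_to(np.asarray(remission, dtype=float), (n,))
    mo = np.broadcast_to(np.asarray(other_mortality, dtype=float), (n,))
    for name, arr in (("incidence", i), ("case_fatality", f), ("remission", r), ("other_mortality", mo)):
        if np.any(arr < 0):
            raise DomainError(f"{name} must be >= 0")
    if not 0 <= p_start < 1:
        raise DomainError("p_start must be in [0, 1)")

    # Living-states generator d/dt (S, C)^T = M (S, C)^T per interval.
    M = np.zeros((n - 1, 2, 2)) if n > 1 else np.zeros((0, 2, 2))
    if n > 1:
        M[:, 0, 0] = -(i[:-1] + mo[:-1])
        M[:, 0, 1] = r[:-1]
        M[:, 1, 0] = i[:-1]
        M[:, 1, 1] = -(f[:-1] + r[:-1] + mo[:-1])
        expM, intM = _putzer_2x2(M)

    S = np.empty(n)
    C = np.empty(n)
    Dd = np.empty(n)
    Do = np.empty(n)
    S[0], C[0], Dd[0], Do[0] = 1.0 - p_start, p_start, 0.0, 0.0
    for t in range(n - 1):
        s, c = S[t], C[t]
        S[t + 1] = expM[t, 0, 0] * s + expM[t, 0, 1] * c
        C[t + 1] = expM[t, 1, 0] * s + expM[t, 1, 1] * c
        s_int = intM[t, 0, 0] * s + intM[t, 0, 1] * c  # person-years in S over the interval
        c_int = intM[t, 1, 0] * s + intM[t, 1, 1] * c
        Dd[t + 1] = Dd[t] + f[t] * c_int
        Do[t + 1] = Do[t] + mo[t] * (s_int + c_int)

    alive = S + C
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(alive > 0, C / np.where(alive > 0, alive, 1.0), 0.0)
    m_d = p * f
    return DiseaseState(ages=ages, S=S, C=C, D_d=Dd, D_o=Do, prevalence=p, disease_mortality=m_d)


def adjust_incidence(epi: DiseaseEpi, pif_by_sex: Mapping[str, np.ndarray]) -> DiseaseEpi:
    """Scale incidence by (1 - PIF) per sex and age; other fields untouched.

    ``pif_by_sex`` maps sex -> per-age PIF array aligned with ``epi.ages``
    (scalars broadcast).  Prevalence and disease mortality must then be
    re-derived via :func:`derive_prevalence_and_mortality`.
    """
    new_by_sex = {}
    for sex, sex_epi in epi.by_sex.items():
        pif = np.broadcast_to(np.asarray(pif_by_sex.get(sex, 0.0), dtype=float), sex_epi.incidence.shape)
        if np.any(pif > 1 + 1e-12):
            raise DomainError("PIF cannot exceed 1")
        new_by_sex[sex] = dataclasses.replace(sex_epi, incidence=sex_epi.incidence * (1.0 - pif))
    return dataclasses.replace(epi, by_sex=new_by_sex)


def derive_prevalence_and_mortality(
    epi: DiseaseEpi, other_mortality_by_sex: Mapping[str, np.ndarray] | None = None
) -> dict[str, DiseaseState]:
    """Re-derive prevalence and disease mortality from incidence and case fatality.

    The illness-death model is solved forward from the input prevalence at
    the first age, so a business-as-usual and a scenario run differ only
    through their incidence series.  Returns one trajectory per sex.
    """
    out = {}
    for sex, sex_epi in epi.by_sex.items():
        mo = 0.0 if other_mortality_by_sex is None else other_mortality_by_sex.get(sex, 0.0)
        out[sex] = solve_illness_death(
            sex_epi.incidence,
            sex_epi.case_fatality,
            sex_epi.remission,
            mo,
            int(epi.ages[0]),
            int(epi.ages[-1]),
            p_start=float(sex_epi.prevalence[0]),
        )
    return out


def epi_from_frame(frame: pd.DataFrame, disease: str) -> DiseaseEpi:
    """Build a DiseaseEpi from the long-format epi CSV schema."""
    required = {
        "disease",
        "sex",
        "age",
        "incidence",
        "prevalence",
        "case_fatality",
        "remission",
        "yld_rate",
        "disability_weight",
    }
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"disease-epi CSV missing columns: {sorted(missing)}")
    rows = frame[frame["disease"] == disease]
    if rows.empty:
        raise SchemaError(f"no rows for disease {disease!r}")
    dws = rows["disability_weight"].unique()
    if len(dws) != 1:
        raise ValidationError(f"{disease}: disability weight must be constant")
    ages = np.sort(rows["age"].unique())
    if np.any(np.diff(ages) != 1):
        raise ValidationError(f"{disease}: ages must be consecutive single years")
    by_sex = {}
    for sex, sub in rows.groupby("sex"):
        sub = sub.sort_values("age")
        if not np.array_equal(sub["age"].to_numpy(), ages):
            raise ValidationError(f"{disease}/{sex}: age grid differs between sexes")
        by_sex[sex] = SexEpi(
            incidence=sub["incidence"].to_numpy(dtype=float),
            prevalence=sub["prevalence"].to_numpy(dtype=float),
            case_fatality=sub["case_fatality"].to_numpy(dtype=float),
            remission=sub["remission"].to_numpy(dtype=float),
            yld_rate=sub["yld_rate"].to_numpy(dtype=float),
        )
    return DiseaseEpi(disease=disease, disability_weight=float(dws[0]), ages=ages, by_sex=by_sex)


def epi_to_frame(epi: DiseaseEpi) -> pd.DataFrame:
    rows = []
    for sex, sex_epi in epi.by_sex.items():
        for j, age in enumerate(epi.ages):
            rows.append(
                {
                    "disease": epi.disease,
                    "sex": sex,
                    "age": int(age),
                    "incidence": sex_epi.incidence[j],
                    "prevalence": sex_epi.prevalence[j],
                    "case_fatality": sex_epi.case_fatality[j],
                    "remission": sex_epi.remission[j],
                    "yld_rate": sex_epi.yld_rate[j],
                    "disability_weight": epi.disability_weight,
                }
            )
    return pd.DataFrame(rows)
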