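"""Population sitting-time exposure: categories, strata and counterfactual transforms.

Exposure is represented on three sitting-time categories (low / moderate /
high) per sex and age band.  Each stratum carries the category occupation
probabilities and the mean sitting minutes per day within each category,
both with standard errors.  Counterfactual scenarios are expressed either
by moving probability mass between categories (``apply_prevalence_shift``)
or by reducing within-category means (``apply_sitting_reduction``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, ValidationError

CATEGORIES: tuple[str, ...] = ("low", "moderate", "high")
#: Half-open minute bounds per category; 240 is moderate, 480 is high.
CATEGORY_BOUNDS: dict[str, tuple[float, float]] = {
    "low": (0.0, 240.0),
    "moderate": (240.0, 480.0),
    "high": (480.0, 1440.0),
}
SEXES: tuple[str, ...] = ("female", "male")
AGE_BANDS: tuple[str, ...] = ("18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+")
#: Closed single-year age ranges spanned by each band.
AGE_BAND_RANGES: dict[str, tuple[int, int]] = {
    "18-24": (18, 24),
    "25-34": (25, 34),
    "35-44": (35, 44),
    "45-54": (45, 54),
    "55-64": (55, 64),
    "65-74": (65, 74),
    "75+": (75, 100),
}

_PROPORTION_SUM_TOL = (0.98, 1.02)

_CSV_COLUMNS = [
    "sex",
    "age_band",
    "category",
    "proportion",
    "proportion_se",
    "mean_minutes",
    "mean_se",
]


def category_index(name: str) -> int:
    try:
        return CATEGORIES.index(name)
    except ValueError:
        raise DomainError(f"unknown sitting-time category {name!r}") from None


def category_of(minutes: float) -> str:
    """Bin daily sitting minutes into a category (half-open bounds).

    ``[0, 240) -> low``, ``[240, 480) -> moderate``, ``[480, 1440] -> high``.
    """
    if not 0.0 <= minutes <= 1440.0:
        raise DomainError(f"minutes/day must be in [0, 1440], got {minutes}")
    if minutes < 240.0:
        return "low"
    if minutes < 480.0:
        return "moderate"
    return "high"


@dataclass(frozen=True)
class ExposureStratum:
    """Category proportions and within-category mean sitting minutes for one sex x age band.

    Arrays are ordered (low, moderate, high).
    """

    sex: str
    age_band: str
    proportion: np.ndarray
    proportion_se: np.ndarray
    mean_minutes: np.ndarray
    mean_se: np.ndarray

    def __post_init__(self) -> None:
        for field in ("proportion", "proportion_se", "mean_minutes", "mean_se"):
            arr = np.asarray(getattr(self, field), dtype=float)
            if arr.shape != (3,):
                raise ValidationError(f"{field} must have shape (3,), got {arr.shape}")
            object.__setattr__(self, field, arr)
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        label = f"{self.sex}/{self.age_band}"
        if np.any(self.proportion < -1e-12) or np.any(self.proportion > 1 + 1e-12):
            raise ValidationError(f"{label}: proportions outside [0, 1]: {self.proportion}")
        total = float(self.proportion.sum())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"{label}: category proportions sum to {total:.6f}, expected 1"
            )
        if np.any(self.proportion_se < 0) or np.any(self.mean_se < 0):
            raise ValidationError(f"{label}: standard errors must be >= 0")
        if not (self.mean_minutes[0] < self.mean_minutes[1] < self.mean_minutes[2]):
            raise ValidationError(
                f"{label}: category means must increase low < moderate < high, "
                f"got {self.mean_minutes}"
            )
        if np.any(self.mean_minutes < 0) or np.any(self.mean_minutes > 1440):
            raise ValidationError(f"{label}: means outside [0, 1440]")

    def replace(self, **changes) -> "ExposureStratum":
        return dataclasses.replace(self, **changes)


def stratum_mean(stratum: ExposureStratum) -> float:
    """Overall mean sitting minutes/day: proportion-weighted category means."""
    return float(np.dot(stratum.proportion, stratum.mean_minutes))


@dataclass(frozen=True)
class ExposureTable:
    """Collection of exposure strata keyed by (sex, age_band)."""

    strata: Mapping[tuple[str, str], ExposureStratum]

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata", dict(self.strata))
        for (sex, band), stratum in self.strata.items():
            if (stratum.sex, stratum.age_band) != (sex, band):
                raise ValidationError(f"stratum key {(sex, band)} does not match its contents")

    def __iter__(self) -> Iterator[ExposureStratum]:
        return iter(self.strata.values())

    def __len__(self) -> int:
        return len(self.strata)

    def stratum(self, sex: str, age_band: str) -> ExposureStratum:
        try:
            return self.strata[(sex, age_band)]
        except KeyError:
            raise KeyError(f"no exposure stratum for sex={sex!r}, age_band={age_band!r}") from None

    @property
    def is_complete(self) -> bool:
        return all((s, b) in self.strata for s in SEXES for b in AGE_BANDS)

    def require_complete(self) -> None:
        missing = [(s, b) for s in SEXES for b in AGE_BANDS if (s, b) not in self.strata]
        if missing:
            raise ValidationError(f"exposure table missing strata: {missing}")

    def map_strata(self, func) -> "ExposureTable":
        return ExposureTable({key: func(st) for key, st in self.strata.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st in self:
            for k, cat in enumerate(CATEGORIES):
                rows.append(
                    {
                        "sex": st.sex,
                        "age_band": st.age_band,
                        "category": cat,
                        "proportion": st.proportion[k],
                        "proportion_se": st.proportion_se[k],
                        "mean_minutes": st.mean_minutes[k],
                        "mean_se": st.mean_se[k],
                    }
                )
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def _stratum_from_rows(sex: str, band: str, rows: pd.DataFrame) -> ExposureStratum:
    cats = set(rows["category"])
    if cats != set(CATEGORIES):
        raise SchemaError(f"{sex}/{band}: expected categories {CATEGORIES}, got {sorted(cats)}")
    rows = rows.set_index("category").loc[list(CATEGORIES)]
    proportion = rows["proportion"].to_numpy(dtype=float)
    total = proportion.sum()
    if not (_PROPORTION_SUM_TOL[0] <= total <= _PROPORTION_SUM_TOL[1]):
        raise ValidationError(
            f"{sex}/{band}: proportions sum to {total:.4f}, outside "
            f"[{_PROPORTION_SUM_TOL[0]}, {_PROPORTION_SUM_TOL[1]}]"
        )
    proportion = proportion / total
    return ExposureStratum(
        sex=sex,
        age_band=band,
        proportion=proportion,
        proportion_se=rows["proportion_se"].to_numpy(dtype=float),
        mean_minutes=rows["mean_minutes"].to_numpy(dtype=float),
        mean_se=rows["mean_se"].to_numpy(dtype=float),
    )


def exposure_table_from_frame(frame: pd.DataFrame) -> ExposureTable:
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"exposure table missing columns: {sorted(missing)}")
    strata = {}
    for (sex, band), rows in frame.groupby(["sex", "age_band"], sort=False):
        if sex not in SEXES:
            raise SchemaError(f"unknown sex {sex!r} in exposure table")
        if band not in AGE_BANDS:
            raise SchemaError(f"unknown age band {band!r} in exposure table")
        strata[(sex, band)] = _stratum_from_rows(sex, band, rows)
    if not strata:
        raise SchemaError("exposure table contains no strata")
    return ExposureTable(strata)


def load_exposure_table(path) -> ExposureTable:
    """Read an exposure CSV (sex, age_band, category, proportion, ... schema).

    Proportions summing within [0.98, 1.02] per stratum are renormalised to 1;
    anything further off raises :class:`ValidationError`.
    """
    frame = pd.read_csv(path)
    return exposure_table_from_frame(frame)


def fixture_exposure_table() -> ExposureTable:
    """The packaged national survey exposure table (2 sexes x 7 age bands)."""
    with resources.files("sbmodel.data").joinpath("table2_exposure.csv").open("rb") as fh:
        table = load_exposure_table(fh)
    table.require_complete()
    return table


def apply_prevalence_shift(
    table: ExposureTable, from_cat: str, to_cat: str, fraction: float
) -> ExposureTable:
    """Move ``fraction`` of each stratum's ``from_cat`` mass into ``to_cat``.

    Movers adopt the destination category's existing mean, so per-category
    means are unchanged and per-stratum mass is conserved exactly.
    """
    i_from, i_to = category_index(from_cat), category_index(to_cat)
    if i_from == i_to:
        raise DomainError("from_cat and to_cat must differ")
    if not 0.0 <= fraction <= 1.0:
        raise DomainError(f"fraction must be in [0, 1], got {fraction}")

    def shift(st: ExposureStratum) -> ExposureStratum:
        p = st.proportion.copy()
        moved = fraction * p[i_from]
        p[i_from] -= moved
        p[i_to] += moved
        return st.replace(proportion=p)

    return table.map_strata(shift)


def apply_sitting_reduction(
    table: ExposureTable, minutes: float, categories: Iterable[str] = ("moderate", "high")
) -> ExposureTable:
    """Reduce the mean sitting minutes of the targeted categories by ``minutes``.

    Means are floored at the category lower bound; proportions are untouched
    (the downstream impact fraction uses a relative-risk shift, not re-binning).
    """
    if minutes < 0:
        raise DomainError(f"minutes must be >= 0, got {minutes}")
    idx = sorted(category_index(c) for c in categories)

    def reduce(st: ExposureStratum) -> ExposureStratum:
        means = st.mean_minutes.copy()
        for k in idx:
            lower = CATEGORY_BOUNDS[CATEGORIES[k]][0]
            means[k] = max(means[k] - minutes, lower)
        return st.replace(mean_minutes=means)

    return table.map_strata(reduce)
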