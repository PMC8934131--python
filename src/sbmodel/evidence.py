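"""Pooling of study-level relative risks and RR sampling distributions.

Per-study relative risks (or hazard ratios, treated interchangeably) are
pooled on the log scale with a random-effects model whose between-study
variance is estimated by restricted maximum likelihood (REML).
Heterogeneity is summarised with the I-squared statistic.  Pooled RRs with
95% CIs are converted into sampling distributions for the Monte-Carlo
layer: a normal on the natural scale by default (truncated at a small
positive floor), optionally a normal on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DomainError, SchemaError, ValidationError
from .exposure import CATEGORIES

Z975 = 1.959964
CONTRASTS = ("moderate_vs_low", "high_vs_low")
#: Floor applied to natural-scale RR draws to keep risks strictly positive.
RR_FLOOR = 1e-6


@dataclass(frozen=True)
class StudyEffect:
    """One study's relative risk for a category contrast, with 95% CI."""

    study_id: str
    disease: str
    category_contrast: str
    rr: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.category_contrast not in CONTRASTS:
            raise ValidationError(f"unknown contrast {self.category_contrast!r}")
        if not (0 < self.ci_low <= self.rr <= self.ci_high):
            raise ValidationError(
                f"{self.study_id}: need 0 < ci_low <= rr <= ci_high, got "
                f"{self.rr} ({self.ci_low}; {self.ci_high})"
            )

    @property
    def log_rr(self) -> float:
        return float(np.log(self.rr))

    @property
    def se_log(self) -> float:
        return float((np.log(self.ci_high) - np.log(self.ci_low)) / (2 * Z975))


@dataclass(frozen=True)
class PooledRR:
    disease: str
    category_contrast: str
    rr: float
    ci_low: float
    ci_high: float
    tau2: float
    i2: float
    k: int

    def __post_init__(self) -> None:
        if self.k < 1 or self.tau2 < 0 or not (0 <= self.i2 <= 1):
            raise ValidationError("invalid pooled-RR summary")
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise ValidationError("pooled CI does not bracket the pooled RR")


def _restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """REML log-likelihood of the random-effects model at a given tau^2."""
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    return -0.5 * (
        float(np.sum(np.log(v + tau2)))
        + float(np.log(np.sum(w)))
        + float(np.sum(w * (y - mu) ** 2))
    )


def reml_tau2(y: Sequence[float], se: Sequence[float]) -> float:
    """Between-study variance maximising the restricted log-likelihood.

    Bounded scalar optimisation over tau^2 >= 0; the boundary tau^2 = 0 is
    always evaluated explicitly so homogeneous inputs return exactly 0.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(se, dtype=float) ** 2
    if np.any(v <= 0):
        raise ValidationError("all standard errors must be > 0 for pooling")
    if len(y) == 1:
        return 0.0
    hi = max(10.0 * float(np.var(y)) + float(v.max()), 1e-3)
    res = optimize.minimize_scalar(
        lambda t: -_restricted_loglik(t, y, v),
        bounds=(0.0, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    candidates = [0.0, float(res.x)]
    return max(candidates, key=lambda t: _restricted_loglik(t, y, v))


def pool_random_effects_reml(effects: Sequence[StudyEffect]) -> PooledRR:
    """Random-effects pooled RR with REML tau^2 on the log scale.

    The pooled log-RR is the inverse-variance weighted mean with weights
    1/(se_i^2 + tau^2); the 95% CI uses the plain normal approximation
    (no small-sample adjustment).  A single study is returned unchanged
    with tau^2 = 0.
    """
    if not effects:
        raise ValidationError("cannot pool an empty study list")
    diseases = {e.disease for e in effects}
    contrasts = {e.category_contrast for e in effects}
    if len(diseases) > 1 or len(contrasts) > 1:
        raise ValidationError("all studies must share disease and contrast")
    disease, contrast = diseases.pop(), contrasts.pop()
    k = len(effects)
    if k == 1:
        only = effects[0]
        if only.se_log <= 0:
            raise ValidationError("non-positive se_log in study effects")
        return PooledRR(
            disease=disease, category_contrast=contrast, rr=only.rr,
            ci_low=only.ci_low, ci_high=only.ci_high, tau2=0.0, i2=0.0, k=1,
        )
    y = np.array([e.log_rr for e in effects])
    se = np.array([e.se_log for e in effects])
    if np.any(se <= 0):
        raise ValidationError("non-positive se_log in study effects")

    tau2 = reml_tau2(y, se)
    w = 1.0 / (se**2 + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(np.sqrt(1.0 / np.sum(w)))
    i2 = i_squared_from_arrays(y, se) if k >= 2 else 0.0
    return PooledRR(
        disease=disease,
        category_contrast=contrast,
        rr=float(np.exp(mu)),
        ci_low=float(np.exp(mu - Z975 * se_mu)),
        ci_high=float(np.exp(mu + Z975 * se_mu)),
        tau2=tau2,
        i2=i2,
        k=k,
    )


def i_squared_from_arrays(y: np.ndarray, se: np.ndarray) -> float:
    w = 1.0 / np.asarray(se, dtype=float) ** 2
    y = np.asarray(y, dtype=float)
    k = len(y)
    if k < 2:
        raise ValidationError("I^2 requires at least two studies")
    mu = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu) ** 2))
    if q <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q)


def i_squared(effects: Sequence[StudyEffect]) -> float:
    """Higgins I^2 from Cochran's Q under fixed-effect weights (log scale)."""
    if len(effects) < 2:
        raise ValidationError("I^2 requires at least two studies")
    y = np.array([e.log_rr for e in effects])
    se = np.array([e.se_log for e in effects])
    return i_squared_from_arrays(y, se)


def rr_sampling_params(
    rr: float, ci_low: float, ci_high: float, scale: str = "natural"
) -> tuple[float, float]:
    """(location, spread) of the RR sampling distribution implied by a 95% CI.

    natural: Normal(rr, (ci_high - ci_low) / (2 * 1.959964)) — truncation to
    positive values is applied at draw time, not here.
    log: Normal(ln rr, (ln ci_high - ln ci_low) / (2 * 1.959964)).
    """
    if not (0 < ci_low <= rr <= ci_high):
        raise DomainError(f"need 0 < ci_low <= rr <= ci_high, got {rr} ({ci_low}; {ci_high})")
    if scale == "natural":
        return float(rr), float((ci_high - ci_low) / (2 * Z975))
    if scale == "log":
        return float(np.log(rr)), float((np.log(ci_high) - np.log(ci_low)) / (2 * Z975))
    raise DomainError(f"unknown scale {scale!r}")


def sample_rr(
    rng: np.random.Generator, rr: float, ci_low: float, ci_high: float, scale: str = "natural"
) -> float:
    """One RR draw; degenerate CIs return the point value exactly."""
    loc, spread = rr_sampling_params(rr, ci_low, ci_high, scale)
    if spread == 0.0:
        return rr
    draw = rng.normal(loc, spread)
    if scale == "log":
        return float(np.exp(draw))
    return float(max(draw, RR_FLOOR))


@dataclass(frozen=True)
class RRTable:
    """Per-disease category RRs (low, moderate, high) with 95% CIs.

    The reference (low) category is pinned to RR 1 with a zero-width CI.
    """

    diseases: Mapping[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for disease, entry in self.diseases.items():
            rr = np.asarray(entry["rr"], dtype=float)
            lo = np.asarray(entry["ci_low"], dtype=float)
            hi = np.asarray(entry["ci_high"], dtype=float)
            for arr in (rr, lo, hi):
                if arr.shape != (3,):
                    raise ValidationError(f"{disease}: RR arrays must have shape (3,)")
            if not (rr[0] == lo[0] == hi[0] == 1.0):
                raise ValidationError(f"{disease}: reference category must be exactly 1 (1; 1)")
            if np.any(rr <= 0) or np.any(lo <= 0) or np.any(hi <= 0):
                raise ValidationError(f"{disease}: RRs must be positive")
            if np.any(lo > rr) or np.any(rr > hi):
                raise ValidationError(f"{disease}: CI must bracket RR")
            clean[disease] = {"rr": rr, "ci_low": lo, "ci_high": hi}
        object.__setattr__(self, "diseases", clean)

    def __contains__(self, disease: str) -> bool:
        return disease in self.diseases

    def disease_names(self) -> list[str]:
        return list(self.diseases)

    def rr(self, disease: str) -> np.ndarray:
        return self.diseases[disease]["rr"]

    def ci(self, disease: str) -> tuple[np.ndarray, np.ndarray]:
        entry = self.diseases[disease]
        return entry["ci_low"], entry["ci_high"]

    def with_rr(self, disease: str, rr: np.ndarray) -> "RRTable":
        """Copy with a disease's point RRs replaced (CIs collapsed onto them)."""
        rr = np.asarray(rr, dtype=float)
        new = dict(self.diseases)
        new[disease] = {"rr": rr, "ci_low": rr.copy(), "ci_high": rr.copy()}
        return RRTable(new)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for disease, entry in self.diseases.items():
            for k, cat in enumerate(CATEGORIES[1:], start=1):
                rows.append(
                    {
                        "disease": disease,
                        "category": cat,
                        "rr": entry["rr"][k],
                        "ci_low": entry["ci_low"][k],
                        "ci_high": entry["ci_high"][k],
                    }
                )
        return pd.DataFrame(rows)


def rr_table_from_frame(frame: pd.DataFrame) -> RRTable:
    required = {"disease", "category", "rr", "ci_low", "ci_high"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"RR table missing columns: {sorted(missing)}")
    diseases: dict[str, dict[str, np.ndarray]] = {}
    for disease, rows in frame.groupby("disease", sort=False):
        cats = set(rows["category"])
        if cats != {"moderate", "high"}:
            raise SchemaError(
                f"{disease}: expected one 'moderate' and one 'high' row, got {sorted(cats)}"
            )
        rows = rows.set_index("category")
        rr = np.array([1.0, rows.loc["moderate", "rr"], rows.loc["high", "rr"]])
        lo = np.array([1.0, rows.loc["moderate", "ci_low"], rows.loc["high", "ci_low"]])
        hi = np.array([1.0, rows.loc["moderate", "ci_high"], rows.loc["high", "ci_high"]])
        diseases[disease] = {"rr": rr, "ci_low": lo, "ci_high": hi}
    return RRTable(diseases)


def load_rr_table(path) -> RRTable:
    return rr_table_from_frame(pd.read_csv(path))


def fixture_rr_table() -> RRTable:
    """The packaged pooled RR table for the five modelled diseases."""
    with resources.files("sbmodel.data").joinpath("table3_rr.csv").open("rb") as fh:
        return load_rr_table(fh)


def load_study_effects(path) -> list[StudyEffect]:
    frame = pd.read_csv(path)
    required = {"study_id", "disease", "contrast", "rr", "ci_low", "ci_high"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"study-effects CSV missing columns: {sorted(missing)}")
    return [
        StudyEffect(
            study_id=str(row.study_id),
            disease=str(row.disease),
            category_contrast=str(row.contrast),
            rr=float(row.rr),
            ci_low=float(row.ci_low),
            ci_high=float(row.ci_high),
        )
        for row in frame.itertuples()
    ]
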