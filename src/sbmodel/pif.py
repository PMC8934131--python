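"""Potential impact fractions from categorical exposure change.

The PIF compares exposure-weighted relative risk between a baseline and a
counterfactual population::

    PIF = (sum_c p_c rr_c - sum_c p'_c rr'_c) / sum_c p_c rr_c

Two routes feed the counterfactual side: moving probability mass between
categories (prevalence shift) and moving a category's RR along a piecewise
log-linear dose-response when its mean sitting time drops within-category
(relative-risk shift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .evidence import RRTable, sample_rr
from .exposure import CATEGORIES, ExposureStratum, category_index

PIF_METHODS = ("prevalence_shift", "rr_shift", "combined")


@dataclass(frozen=True)
class PifInput:
    """Baseline/counterfactual exposure for one stratum plus one disease's RRs."""

    baseline: ExposureStratum
    counterfactual: ExposureStratum
    rr: np.ndarray  # (3,) low, moderate, high
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.baseline.sex, self.baseline.age_band) != (
            self.counterfactual.sex,
            self.counterfactual.age_band,
        ):
            raise ValidationError("baseline and counterfactual must describe the same stratum")
        rr = np.asarray(self.rr, dtype=float)
        if rr.shape != (3,) or rr[0] != 1.0 or np.any(rr <= 0):
            raise ValidationError(f"per-category RRs must be (1, m, h) > 0, got {rr}")
        object.__setattr__(self, "rr", rr)
        for name in ("ci_low", "ci_high"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, np.asarray(val, dtype=float))


@dataclass(frozen=True)
class PifResult:
    sex: str
    age_band: str
    disease: str
    pif: float

    def __post_init__(self) -> None:
        if self.pif > 1 + 1e-12:
            raise ValidationError(f"PIF cannot exceed 1, got {self.pif}")


def pif_categorical(p_base, p_cf, rr) -> float:
    """PIF of a categorical exposure change at fixed per-category RRs."""
    p_base = np.asarray(p_base, dtype=float)
    p_cf = np.asarray(p_cf, dtype=float)
    rr = np.asarray(rr, dtype=float)
    for p in (p_base, p_cf):
        if abs(p.sum() - 1.0) > 1e-6:
            raise DomainError(f"proportions must sum to 1, got {p.sum():.6f}")
    if np.any(rr <= 0):
        raise DomainError("relative risks must be positive")
    base = float(np.dot(p_base, rr))
    cf = float(np.dot(p_cf, rr))
    return (base - cf) / base


def _pif_two_sided(p_base, rr_base, p_cf, rr_cf) -> float:
    base = float(np.dot(p_base, rr_base))
    return (base - float(np.dot(p_cf, rr_cf))) / base


def rr_shift_for_mean_change(
    category: str, rr: np.ndarray, anchor_means: np.ndarray, delta_minutes: float
) -> float:
    """Move a category's RR down a piecewise log-linear dose-response curve.

    The curve passes through (mean_low, ln 1), (mean_moderate, ln rr_mod),
    (mean_high, ln rr_high); the targeted category's log-RR is reduced by
    its segment slope times ``delta_minutes`` and floored at RR = 1.
    """
    rr = np.asarray(rr, dtype=float)
    anchors = np.asarray(anchor_means, dtype=float)
    if delta_minutes < 0:
        raise DomainError("delta_minutes must be >= 0")
    if not (anchors[0] < anchors[1] < anchors[2]):
        raise DomainError(f"anchor means must be strictly increasing, got {anchors}")
    k = category_index(category)
    if k == 0:
        return 1.0  # reference category sits at the curve origin
    slope = (np.log(rr[k]) - np.log(rr[k - 1])) / (anchors[k] - anchors[k - 1])
    log_shifted = np.log(rr[k]) - slope * delta_minutes
    return float(max(np.exp(log_shifted), 1.0))


def shifted_rr_vector(input: PifInput) -> np.ndarray:
    """Per-category RRs after within-category sitting reductions.

    The reduction per category is the baseline-minus-counterfactual mean;
    anchors are the baseline stratum's own category means.
    """
    deltas = input.baseline.mean_minutes - input.counterfactual.mean_minutes
    if np.any(deltas < -1e-9):
        raise DomainError("counterfactual means must not exceed baseline means for rr_shift")
    rr_cf = input.rr.copy()
    for k, cat in enumerate(CATEGORIES):
        if deltas[k] > 0:
            rr_cf[k] = rr_shift_for_mean_change(
                cat, input.rr, input.baseline.mean_minutes, float(deltas[k])
            )
    return rr_cf


def pif_for_scenario(input: PifInput, method: str, disease: str = "") -> PifResult:
    """PIF for one stratum x disease under the requested counterfactual route."""
    if method not in PIF_METHODS:
        raise DomainError(f"unknown PIF method {method!r}; expected one of {PIF_METHODS}")
    p_base = input.baseline.proportion
    rr_base = input.rr
    if method == "prevalence_shift":
        value = _pif_two_sided(p_base, rr_base, input.counterfactual.proportion, rr_base)
    elif method == "rr_shift":
        value = _pif_two_sided(p_base, rr_base, p_base, shifted_rr_vector(input))
    else:  # combined
        value = _pif_two_sided(
            p_base, rr_base, input.counterfactual.proportion, shifted_rr_vector(input)
        )
    return PifResult(
        sex=input.baseline.sex, age_band=input.baseline.age_band, disease=disease, pif=value
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return float(mu), float(np.sqrt(sigma2))


def sample_category_means(
    rng: np.random.Generator, means: np.ndarray, ses: np.ndarray
) -> np.ndarray:
    """Lognormal draws of category mean minutes, moment-matched to (mean, se).

    Zero-SE entries are returned exactly; draws are clipped into the category
    bounds so the ordering invariant survives sampling.
    """
    from .exposure import CATEGORY_BOUNDS

    out = np.asarray(means, dtype=float).copy()
    for k, cat in enumerate(CATEGORIES):
        if ses[k] > 0:
            mu, sigma = _lognormal_params(means[k], ses[k])
            lo, hi = CATEGORY_BOUNDS[cat]
            out[k] = float(np.clip(rng.lognormal(mu, sigma), lo + 1e-9, hi - 1e-9))
    return out


def pif_monte_carlo(
    input: PifInput,
    draws: int,
    seed: int,
    method: str = "prevalence_shift",
    rr_scale: str = "natural",
) -> np.ndarray:
    """Empirical PIF sample under RR and sitting-time parameter uncertainty.

    Per draw, RRs are sampled from the distribution implied by their CIs and
    category means from moment-matched lognormals; the deterministic PIF is
    then evaluated at the sampled parameters.  Deterministic inputs (zero
    spreads) reproduce the point PIF in every draw.
    """
    if draws < 1:
        raise DomainError("draws must be >= 1")
    if input.ci_low is None or input.ci_high is None:
        ci_low = input.rr
        ci_high = input.rr
    else:
        ci_low, ci_high = input.ci_low, input.ci_high
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = np.empty(draws)
    for d in range(draws):
        rr = np.array(
            [
                sample_rr(rng, input.rr[k], ci_low[k], ci_high[k], rr_scale)
                for k in range(3)
            ]
        )
        rr[0] = 1.0
        base_means = sample_category_means(
            rng, input.baseline.mean_minutes, input.baseline.mean_se
        )
        base_means = np.sort(base_means)  # preserve low < moderate < high under sampling
        deltas = input.baseline.mean_minutes - input.counterfactual.mean_minutes
        cf_means = np.maximum(base_means - deltas, 1e-9)
        base = input.baseline.replace(mean_minutes=base_means)
        cf = input.counterfactual.replace(mean_minutes=cf_means)
        draw_input = PifInput(baseline=base, counterfactual=cf, rr=rr)
        out[d] = pif_for_scenario(draw_input, method).pif
    return out
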