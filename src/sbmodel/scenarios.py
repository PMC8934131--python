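"""Scenario definitions, end-to-end runs and the coverage threshold analysis.

Four built-in scenarios are provided:

1. eliminate_excess — everyone in the moderate and high categories moves to
   the low category (the maximum-benefit envelope);
2. prevalence_shift — 30% of the high category moves to moderate;
3. prevalence_shift — 30% of the moderate category moves to low;
4. sitting_reduction — a 36.3 minute/day reduction within the moderate and
   high categories, translated through the relative-risk shift.

Coverage scales the affected fraction of the target population as a
mixture of shifted and baseline exposure, which makes the PIF linear in
coverage and the resulting HALY gain monotone (the basis of the bisection
threshold analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import DomainError, ValidationError
from .evidence import RRTable
from .exposure import (
    ExposureTable,
    apply_prevalence_shift,
    apply_sitting_reduction,
)
from .lifetable import (
    CostInputs,
    LifeTableModel,
    PopulationTable,
    build_model,
    run_comparison,
)
from .disease_model import DiseaseDefinition, DiseaseEpi
from .pif import PifInput, pif_for_scenario

SCENARIO_KINDS = ("eliminate_excess", "prevalence_shift", "sitting_reduction", "threshold")
#: Within-category reduction (minutes/day) observed in the workplace trial
#: driving scenario 4.
TRIAL_REDUCTION_MINUTES = 36.3


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    kind: str
    fraction_moved: float | None = None
    from_category: str | None = None
    to_category: str | None = None
    minutes_reduced: float | None = None
    target_categories: tuple[str, ...] = ("moderate", "high")
    target_halys: float | None = None
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValidationError(f"unknown scenario kind {self.kind!r}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValidationError("coverage must be in [0, 1]")
        if self.kind == "prevalence_shift":
            if self.fraction_moved is None or self.from_category is None or self.to_category is None:
                raise ValidationError(f"{self.id}: prevalence_shift needs fraction/from/to")
        if self.kind in ("sitting_reduction", "threshold") and self.minutes_reduced is None:
            raise ValidationError(f"{self.id}: needs minutes_reduced")
        if self.kind == "threshold" and self.target_halys is None:
            raise ValidationError(f"{self.id}: threshold needs target_halys")


def builtin_scenarios() -> list[ScenarioSpec]:
    return [
        ScenarioSpec(id="1", kind="eliminate_excess"),
        ScenarioSpec(
            id="2",
            kind="prevalence_shift",
            fraction_moved=0.30,
            from_category="high",
            to_category="moderate",
        ),
        ScenarioSpec(
            id="3",
            kind="prevalence_shift",
            fraction_moved=0.30,
            from_category="moderate",
            to_category="low",
        ),
        ScenarioSpec(
            id="4",
            kind="sitting_reduction",
            minutes_reduced=TRIAL_REDUCTION_MINUTES,
            target_categories=("moderate", "high"),
        ),
    ]


def get_builtin_scenario(scenario_id: str) -> ScenarioSpec:
    for spec in builtin_scenarios():
        if spec.id == str(scenario_id):
            return spec
    raise DomainError(f"unknown built-in scenario {scenario_id!r}")


@dataclass(frozen=True)
class ModelInputs:
    """Everything an end-to-end scenario run needs."""

    exposure: ExposureTable
    rr: RRTable
    population: PopulationTable
    diseases: tuple[tuple[DiseaseDefinition, DiseaseEpi], ...]
    costs: CostInputs

    def model(self) -> LifeTableModel:
        return build_model(self.population, self.diseases, self.costs)

    def replace(self, **changes) -> "ModelInputs":
        return replace(self, **changes)


def counterfactual_exposure(spec: ScenarioSpec, table: ExposureTable) -> tuple[ExposureTable, str]:
    """Counterfactual exposure table plus the PIF method it implies."""
    if spec.kind == "eliminate_excess":
        cf = apply_prevalence_shift(table, "moderate", "low", 1.0)
        cf = apply_prevalence_shift(cf, "high", "low", 1.0)
        return cf, "prevalence_shift"
    if spec.kind == "prevalence_shift":
        cf = apply_prevalence_shift(table, spec.from_category, spec.to_category, spec.fraction_moved)
        return cf, "prevalence_shift"
    if spec.kind in ("sitting_reduction", "threshold"):
        cf = apply_sitting_reduction(table, spec.minutes_reduced, spec.target_categories)
        return cf, "rr_shift"
    raise DomainError(f"unknown scenario kind {spec.kind!r}")


def compute_pifs(
    spec: ScenarioSpec,
    exposure: ExposureTable,
    rr_table: RRTable,
    diseases: tuple[tuple[DiseaseDefinition, DiseaseEpi], ...],
) -> dict[str, dict[tuple[str, str], float]]:
    """Per-disease, per-(sex, age band) PIFs for a scenario.

    Coverage scales the PIF linearly (a ``coverage`` : ``1 - coverage``
    mixture of shifted and baseline exposure shares the baseline
    denominator).
    """
    cf_table, method = counterfactual_exposure(spec, exposure)
    out: dict[str, dict[tuple[str, str], float]] = {}
    for defn, _ in diseases:
        name = defn.name
        if name not in rr_table:
            raise ValidationError(f"no relative risks for disease {name!r}")
        ci_low, ci_high = rr_table.ci(name)
        per_stratum: dict[tuple[str, str], float] = {}
        for stratum in exposure:
            if stratum.sex not in defn.sexes:
                continue
            cf = cf_table.stratum(stratum.sex, stratum.age_band)
            pif_input = PifInput(
                baseline=stratum,
                counterfactual=cf,
                rr=rr_table.rr(name),
                ci_low=ci_low,
                ci_high=ci_high,
            )
            result = pif_for_scenario(pif_input, method, disease=name)
            per_stratum[(stratum.sex, stratum.age_band)] = spec.coverage * result.pif
        out[name] = per_stratum
    return out


def run_scenario(
    spec: ScenarioSpec,
    inputs: ModelInputs,
    mc=None,
    horizon_years: int = 1,
    discount_rate: float = 0.0,
):
    """Run one scenario end-to-end.

    Returns an :class:`OutputSummary` for a deterministic run, or the
    Monte-Carlo summary when an uncertainty config is supplied.
    """
    if mc is not None:
        from .uncertainty import run_monte_carlo

        return run_monte_carlo(spec, inputs, mc, horizon_years=horizon_years,
                               discount_rate=discount_rate)
    pifs = compute_pifs(spec, inputs.exposure, inputs.rr, inputs.diseases)
    return run_comparison(inputs.model(), pifs, horizon_years, discount_rate)


@dataclass(frozen=True)
class ThresholdResult:
    coverage: float
    achieved_halys: float
    iterations: int
    converged: bool
    target_halys: float

    def __post_init__(self) -> None:
        if self.converged and self.target_halys > 0:
            rel = abs(self.achieved_halys - self.target_halys) / self.target_halys
            if rel >= 1e-3:
                raise ValidationError("converged threshold result misses its target")


def threshold_coverage(
    minutes_reduced: float,
    target_halys: float,
    inputs: ModelInputs,
    horizon_years: int = 1,
    discount_rate: float = 0.0,
    rel_tol: float = 1e-3,
    max_iter: int = 60,
) -> ThresholdResult:
    """Bisection on coverage for a sitting-reduction scenario to hit a HALY target.

    HALYs gained are monotone increasing in coverage, so bisection on
    [0, 1] is valid.  Unreachable targets return ``converged = False`` with
    the HALY gain at full coverage.
    """
    if target_halys <= 0:
        raise DomainError("target_halys must be > 0")

    def halys_at(coverage: float) -> float:
        spec = ScenarioSpec(
            id="threshold",
            kind="sitting_reduction",
            minutes_reduced=minutes_reduced,
            coverage=coverage,
        )
        summary = run_scenario(spec, inputs, horizon_years=horizon_years,
                               discount_rate=discount_rate)
        return summary.total("halys_gained")

    hi_val = halys_at(1.0)
    if hi_val < target_halys:
        return ThresholdResult(
            coverage=1.0,
            achieved_halys=hi_val,
            iterations=1,
            converged=False,
            target_halys=target_halys,
        )
    lo, hi = 0.0, 1.0
    value = hi_val
    mid = 1.0
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        value = halys_at(mid)
        if abs(value - target_halys) / target_halys < rel_tol:
            return ThresholdResult(
                coverage=mid,
                achieved_halys=value,
                iterations=it + 1,
                converged=True,
                target_halys=target_halys,
            )
        if value < target_halys:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(
        coverage=mid, achieved_halys=value, iterations=max_iter + 1,
        converged=False, target_halys=target_halys,
    )
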