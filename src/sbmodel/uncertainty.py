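"""Second-order (parameter) Monte-Carlo uncertainty propagation.

Each draw perturbs the sampled inputs (relative risks, category mean
sitting minutes, category proportions — optionally costs), re-runs the
deterministic pipeline and records every output metric; summaries report
the empirical mean with a 2.5/97.5 percentile uncertainty interval.
Draws are keyed by (seed, draw_index) through ``numpy.random.SeedSequence``
so results are reproducible regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import DomainError
from .evidence import RRTable, sample_rr
from .exposure import ExposureStratum, ExposureTable
from .pif import sample_category_means

if TYPE_CHECKING:
    from .scenarios import ModelInputs, ScenarioSpec

DEFAULT_DRAWS = 2000
PROPORTION_SAMPLING = ("truncated_normal_renormalised", "fixed")


@dataclass(frozen=True)
class McConfig:
    draws: int = DEFAULT_DRAWS
    seed: int = 0
    rr_scale: str = "natural"
    proportion_sampling: str = "truncated_normal_renormalised"
    sample_costs: bool = False
    cost_cv: float = 0.2  # coefficient of variation for optional gamma cost sampling

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise DomainError("draws must be >= 1")
        if self.proportion_sampling not in PROPORTION_SAMPLING:
            raise DomainError(f"unknown proportion sampling {self.proportion_sampling!r}")
        if self.rr_scale not in ("natural", "log"):
            raise DomainError(f"unknown rr scale {self.rr_scale!r}")


@dataclass(frozen=True)
class McSummary:
    """Per-metric mean and 95% UI over Monte-Carlo draws."""

    frame: pd.DataFrame  # index (metric, sex, disease); columns mean, ui_low, ui_high
    draws_used: int

    def total(self, metric: str) -> pd.Series:
        return self.frame.loc[(metric, "total", "all")]

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["draws_used"] = self.draws_used
        return out


def _sample_stratum(rng: np.random.Generator, st: ExposureStratum, cfg: McConfig) -> ExposureStratum:
    means = sample_category_means(rng, st.mean_minutes, st.mean_se)
    means = np.sort(means)
    if cfg.proportion_sampling == "truncated_normal_renormalised" and np.any(st.proportion_se > 0):
        p = np.maximum(rng.normal(st.proportion, st.proportion_se), 0.0)
        total = p.sum()
        p = p / total if total > 0 else st.proportion
    else:
        p = st.proportion
    return st.replace(proportion=p, mean_minutes=means)


def _sample_rr_table(rng: np.random.Generator, table: RRTable, cfg: McConfig) -> RRTable:
    out = table
    for disease in table.disease_names():
        rr = table.rr(disease)
        lo, hi = table.ci(disease)
        drawn = rr.copy()
        for k in range(1, 3):
            drawn[k] = sample_rr(rng, rr[k], lo[k], hi[k], cfg.rr_scale)
        out = out.with_rr(disease, drawn)
    return out


def _sample_costs(rng: np.random.Generator, costs, cfg: McConfig):
    from .lifetable import CostInputs

    if not cfg.sample_costs:
        return costs
    new = {}
    cv2 = cfg.cost_cv**2
    shape = 1.0 / cv2
    for disease, per_sex in costs.costs.items():
        new[disease] = {}
        for sex, arr in per_sex.items():
            scale = np.asarray(arr, dtype=float) * cv2
            drawn = np.where(scale > 0, rng.gamma(shape, np.where(scale > 0, scale, 1.0)), arr)
            new[disease][sex] = drawn
    return CostInputs(costs=new, bases=dict(costs.bases))


def sample_inputs(inputs: "ModelInputs", mc: McConfig, draw_index: int) -> "ModelInputs":
    """Perturbed copy of the inputs, a pure function of (seed, draw_index)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=mc.seed, spawn_key=(draw_index,)))
    exposure = ExposureTable(
        {key: _sample_stratum(rng, st, mc) for key, st in inputs.exposure.strata.items()}
    )
    rr = _sample_rr_table(rng, inputs.rr, mc)
    costs = _sample_costs(rng, inputs.costs, mc)
    return inputs.replace(exposure=exposure, rr=rr, costs=costs)


def run_monte_carlo(
    spec: "ScenarioSpec",
    inputs: "ModelInputs",
    mc: McConfig,
    horizon_years: int = 1,
    discount_rate: float = 0.0,
) -> McSummary:
    """Run the full pipeline once per draw and summarise every output metric."""
    from .scenarios import run_scenario

    samples = []
    for d in range(mc.draws):
        perturbed = sample_inputs(inputs, mc, d)
        summary = run_scenario(perturbed_spec(spec), perturbed,
                               horizon_years=horizon_years, discount_rate=discount_rate)
        samples.append(summary.to_series())
    stacked = pd.concat(samples, axis=1)
    frame = pd.DataFrame(
        {
            "mean": stacked.mean(axis=1),
            "ui_low": stacked.quantile(0.025, axis=1),
            "ui_high": stacked.quantile(0.975, axis=1),
        }
    )
    return McSummary(frame=frame, draws_used=mc.draws)


def perturbed_spec(spec: "ScenarioSpec") -> "ScenarioSpec":
    # Scenario definitions carry no sampled quantities; hook kept for clarity.
    return spec
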