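"""Probabilistic Monte Carlo cost model.

Each iteration resamples every adjusted mean from its tagged sampling
distribution (normal truncated at zero by default; ``fixed`` cells pass
through unchanged), converts quantities to 2016/17 GBP with the weighted
unit costs, and takes the cost difference (revealed PlGF testing minus
usual care) per resource category and subgroup cell. Cell differences
are weighted by the subgroup mix to a per-woman figure; severe maternal
adverse events are drawn per arm from mean-preserving beta
distributions, giving events avoided per 1000 women; and the two are
combined into net monetary benefit at a grid of willingness-to-pay
values to trace the cost-effectiveness acceptability curve (CEAC).

Sign convention throughout: a negative cost difference is a saving, so
"probability cost-saving" is the fraction of iterations strictly below
zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .costing import UnitCostTable
from .schema import (
    ARMS,
    CATEGORIES,
    INFANT_CATEGORIES,
    MATERNAL_CATEGORIES,
    SUBGROUPS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PSAConfig",
    "AdverseEventInput",
    "PSAResult",
    "subgroup_weights",
    "draw_iteration",
    "cell_cost_difference",
    "weight_costs",
    "prob_cost_saving",
    "adverse_event_draws",
    "ceac",
    "test_price_sweep",
    "run_psa",
]

_MATERNAL_IDX = [CATEGORIES.index(c) for c in MATERNAL_CATEGORIES]
_INFANT_IDX = [CATEGORIES.index(c) for c in INFANT_CATEGORIES]


@dataclass(frozen=True)
class PSAConfig:
    n_iterations: int = 5000
    seed: int = 0
    test_cost: float = 70.0
    test_cost_sweep: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0)
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 50001, 1000))
    weights_mode: str = "pooled"

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.weights_mode not in ("pooled", "per-arm"):
            raise ValueError("weights_mode must be 'pooled' or 'per-arm'")

    @classmethod
    def from_config(cls, config: Mapping, seed: int | None = None) -> "PSAConfig":
        p = config.get("psa", {})
        wtp_max = int(p.get("wtp_max", 50000))
        wtp_step = int(p.get("wtp_step", 1000))
        return cls(
            n_iterations=int(p.get("iterations", 5000)),
            seed=int(seed if seed is not None else config.get("seed", 0)),
            test_cost=float(p.get("test_cost", 70.0)),
            test_cost_sweep=tuple(float(x) for x in p.get("test_cost_sweep", (50, 100, 150, 200))),
            wtp_grid=tuple(float(x) for x in range(0, wtp_max + 1, wtp_step)),
            weights_mode=str(p.get("weights_mode", "pooled")),
        )


@dataclass(frozen=True)
class AdverseEventInput:
    """Severe maternal adverse events per arm, as events / denominator."""

    events_usual: int = 24
    n_usual: int = 447
    events_plgf: int = 22
    n_plgf: int = 573

    def __post_init__(self):
        for r, n in ((self.events_usual, self.n_usual), (self.events_plgf, self.n_plgf)):
            if not 0 <= r <= n:
                raise ValueError(f"invalid event counts {r}/{n}")


def subgroup_weights(records: pd.DataFrame, mode: str = "pooled") -> np.ndarray:
    """Observed subgroup proportions, the weighting vector of the model.

    ``pooled`` returns a 9-vector over both arms combined; ``per-arm``
    returns a (9, 2) matrix with one column per arm (usual, revealed).
    """
    def _props(df: pd.DataFrame) -> np.ndarray:
        counts = np.array(
            [
                ((df["plgf_category"] == b) & (df["diagnosis"] == d)).sum()
                for b, d in SUBGROUPS
            ],
            dtype=float,
        )
        return counts / counts.sum()

    if mode == "pooled":
        return _props(records)
    if mode == "per-arm":
        return np.column_stack([_props(records[records["arm"] == a]) for a in ARMS])
    raise ValueError("mode must be 'pooled' or 'per-arm'")


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _means_grid(means_df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Reshape the adjusted-means table to (category, cell, arm) arrays."""
    mean = np.full((len(CATEGORIES), len(SUBGROUPS), 2), np.nan)
    se = np.full_like(mean, np.nan)
    lookup = {
        (r.category, r.plgf_category, r.diagnosis, r.arm): (r.mean, r.se)
        for r in means_df.itertuples()
    }
    for i, cat in enumerate(CATEGORIES):
        for j, (b, d) in enumerate(SUBGROUPS):
            for a, arm in enumerate(ARMS):
                key = (cat, b, d, arm)
                if key not in lookup:
                    raise ValueError(f"adjusted means missing cell {key}")
                mean[i, j, a], se[i, j, a] = lookup[key]
    if np.isnan(mean).any() or np.isnan(se).any():
        raise ValueError("adjusted means contain missing values")
    return mean, se


def _sample_quantities(
    mean: np.ndarray, se: np.ndarray, rng: np.random.Generator, n_iter: int
) -> np.ndarray:
    """Truncated-normal draws per grid entry; zero-SE cells are fixed."""
    out = np.broadcast_to(mean, (n_iter, *mean.shape)).copy()
    positive = se > 0
    if positive.any():
        m = mean[positive]
        s = se[positive]
        a = (0.0 - m) / s
        draws = stats.truncnorm.rvs(
            a=np.broadcast_to(a, (n_iter, *a.shape)),
            b=np.inf,
            loc=np.broadcast_to(m, (n_iter, *m.shape)),
            scale=np.broadcast_to(s, (n_iter, *s.shape)),
            random_state=rng,
        )
        out[:, positive] = draws
    return out


def draw_iteration(
    means_df: pd.DataFrame, unit_costs: UnitCostTable, rng: np.random.Generator
) -> pd.DataFrame:
    """One Monte Carlo iteration: sampled quantity and cost per
    (category, subgroup, arm)."""
    mean, se = _means_grid(means_df)
    q = _sample_quantities(mean, se, rng, 1)[0]
    uc = np.array([unit_costs.category_costs[c] for c in CATEGORIES])
    rows = []
    for i, cat in enumerate(CATEGORIES):
        for j, (b, d) in enumerate(SUBGROUPS):
            for a, arm in enumerate(ARMS):
                rows.append(
                    {
                        "category": cat,
                        "plgf_category": b,
                        "diagnosis": d,
                        "arm": arm,
                        "quantity": q[i, j, a],
                        "cost": q[i, j, a] * uc[i],
                    }
                )
    return pd.DataFrame(rows)


def cell_cost_difference(sampled: pd.DataFrame, cell: tuple[str, str], category: str) -> float:
    """Sampled cost difference (revealed minus usual) for one cell."""
    b, d = cell
    sub = sampled[
        (sampled["category"] == category)
        & (sampled["plgf_category"] == b)
        & (sampled["diagnosis"] == d)
    ]
    cost = sub.set_index("arm")["cost"]
    return float(cost["revealed"] - cost["usual"])


def _check_weights(weights: np.ndarray) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("subgroup weights must be nonnegative")
    if np.any(np.abs(weights.sum(axis=0) - 1.0) > 1e-9):
        raise ValueError("subgroup weights must sum to 1 (within 1e-9)")
    return weights


def weight_costs(cell_differences, weights) -> np.ndarray | float:
    """Per-woman figure: weight-sum of the 9 cell differences."""
    weights = _check_weights(np.asarray(weights, dtype=float))
    values = np.asarray(cell_differences, dtype=float)
    return values @ weights


def prob_cost_saving(iteration_values) -> float:
    """Fraction of iterations strictly below zero (ties are not savings)."""
    values = np.asarray(iteration_values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one iteration")
    return float(np.mean(values < 0))


def adverse_event_draws(
    inp: AdverseEventInput, n_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Beta-distributed adverse-event rates per arm and events avoided.

    The default rule Beta(r, n - r) preserves the observed mean r/n.
    When an arm has zero events that rule is undefined, so the draw
    switches to the Jeffreys-style Beta(r + 1/2, n - r + 1/2) with a
    logged note. Events avoided per 1000 = 1000 * (p_usual - p_plgf).
    """

    def _draw(r: int, n: int) -> np.ndarray:
        if r == 0 or r == n:
            logger.info(
                "degenerate event count %d/%d: using Beta(r+1/2, n-r+1/2)", r, n
            )
            return rng.beta(r + 0.5, n - r + 0.5, size=n_iter)
        return rng.beta(r, n - r, size=n_iter)

    p_usual = _draw(inp.events_usual, inp.n_usual)
    p_plgf = _draw(inp.events_plgf, inp.n_plgf)
    avoided_per_1000 = 1000.0 * (p_usual - p_plgf)
    return p_usual, p_plgf, avoided_per_1000


def ceac(
    cost_draws_per_1000: np.ndarray,
    events_avoided_per_1000: np.ndarray,
    wtp_grid: Sequence[float],
) -> pd.DataFrame:
    """Probability that net monetary benefit is positive at each
    willingness-to-pay: NMB = wtp * events avoided - cost, per 1000."""
    cost = np.asarray(cost_draws_per_1000, dtype=float)
    eff = np.asarray(events_avoided_per_1000, dtype=float)
    if cost.shape != eff.shape:
        raise ValueError("cost and effect draws must align per iteration")
    rows = [
        {"wtp": float(lam), "probability": float(np.mean(lam * eff - cost > 0))}
        for lam in wtp_grid
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """All per-iteration draws and derived summaries of one model run."""

    config: PSAConfig
    weights: np.ndarray  # (9,) pooled or (9, 2) per-arm
    cell_diff: np.ndarray  # (n_iter, n_categories, 9)
    weighted_by_category: np.ndarray  # (n_iter, n_categories)
    maternal: np.ndarray  # (n_iter,) weighted per-woman, excl. test
    infant: np.ndarray
    combined: np.ndarray
    combined_with_test: np.ndarray
    group_cell: dict  # group -> (n_iter, 9) per-cell totals
    p_usual: np.ndarray
    p_plgf: np.ndarray
    events_avoided_per_1000: np.ndarray
    ceac_points: pd.DataFrame
    sweep: pd.DataFrame = field(default=None)
    adverse_input: AdverseEventInput = field(default=None)

    @property
    def probabilities(self) -> dict[str, float]:
        return {
            "maternal": prob_cost_saving(self.maternal),
            "infant": prob_cost_saving(self.infant),
            "combined": prob_cost_saving(self.combined),
            "combined_with_test": prob_cost_saving(self.combined_with_test),
        }

    @property
    def mean_savings(self) -> dict[str, float]:
        return {
            "maternal": float(self.maternal.mean()),
            "infant": float(self.infant.mean()),
            "combined": float(self.combined.mean()),
            "combined_with_test": float(self.combined_with_test.mean()),
        }

    @property
    def dominant(self) -> bool:
        """Cheaper on average (test included) and more effective."""
        return bool(
            self.combined_with_test.mean() < 0
            and self.events_avoided_per_1000.mean() > 0
        )


def test_price_sweep(result: PSAResult, prices: Sequence[float]) -> pd.DataFrame:
    """Cost-saving probabilities (maternal / infant / combined, each with
    the test price added) over a grid of per-test prices."""
    rows = []
    for price in prices:
        if price < 0:
            raise ValueError("test price must be nonnegative")
        rows.append(
            {
                "test_cost": float(price),
                "maternal": prob_cost_saving(result.maternal + price),
                "infant": prob_cost_saving(result.infant + price),
                "combined": prob_cost_saving(result.combined + price),
            }
        )
    return pd.DataFrame(rows)


def run_psa(
    means_df: pd.DataFrame,
    unit_costs: UnitCostTable,
    adverse_input: AdverseEventInput,
    config: PSAConfig,
    weights: np.ndarray,
) -> PSAResult:
    """Run the full probabilistic model; deterministic given the seed."""
    weights = _check_weights(np.asarray(weights, dtype=float))
    per_arm = weights.ndim == 2
    if per_arm != (config.weights_mode == "per-arm"):
        raise ValueError("weights shape does not match weights_mode")
    rng = np.random.default_rng(config.seed)
    mean, se = _means_grid(means_df)
    q = _sample_quantities(mean, se, rng, config.n_iterations)
    uc = np.array([unit_costs.category_costs[c] for c in CATEGORIES])
    cost = q * uc[None, :, None, None]

    cell_diff = cost[..., 1] - cost[..., 0]  # (n_iter, cat, 9)
    if per_arm:
        weighted_by_category = (
            cost[..., 1] @ weights[:, 1] - cost[..., 0] @ weights[:, 0]
        )
    else:
        weighted_by_category = cell_diff @ weights

    maternal = weighted_by_category[:, _MATERNAL_IDX].sum(axis=1)
    infant = weighted_by_category[:, _INFANT_IDX].sum(axis=1)
    combined = maternal + infant
    combined_with_test = combined + config.test_cost

    group_cell = {
        "maternal": cell_diff[:, _MATERNAL_IDX, :].sum(axis=1),
        "infant": cell_diff[:, _INFANT_IDX, :].sum(axis=1),
        "combined": cell_diff.sum(axis=1),
    }

    p_usual, p_plgf, avoided = adverse_event_draws(
        adverse_input, config.n_iterations, rng
    )
    ceac_points = ceac(1000.0 * combined_with_test, avoided, config.wtp_grid)

    result = PSAResult(
        config=config,
        weights=weights,
        cell_diff=cell_diff,
        weighted_by_category=weighted_by_category,
        maternal=maternal,
        infant=infant,
        combined=combined,
        combined_with_test=combined_with_test,
        group_cell=group_cell,
        p_usual=p_usual,
        p_plgf=p_plgf,
        events_avoided_per_1000=avoided,
        ceac_points=ceac_points,
        adverse_input=adverse_input,
    )
    result.sweep = test_price_sweep(result, config.test_cost_sweep)
    return result
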