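"""Publication-shaped outputs and national-scale extrapolation.

Writes the cost-difference tables (rows: resource category x statistic
{Actual, Weighted, Percentage<0}; columns: the nine PlGF x diagnosis
cells plus a row total), the test-price sensitivity table, the CEAC
points, a national scaling summary and run metadata. Values are stored
as raw floats; :func:`format_gbp` rounds to whole pounds for display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .psa import PSAResult, prob_cost_saving
from .schema import (
    CATEGORIES,
    INFANT_CATEGORIES,
    MATERNAL_CATEGORIES,
    SUBGROUP_LABELS,
)

__all__ = [
    "ScalingInputs",
    "scale_to_population",
    "proportion_pct",
    "format_gbp",
    "table_maternal",
    "table_infant_combined",
    "render_outputs",
]


@dataclass(frozen=True)
class ScalingInputs:
    """National extrapolation inputs: births, eligibility fractions and
    the per-woman saving with the test cost included."""

    annual_births: int = 646794
    p_suspected: float = 0.10
    p_preterm_presentation: float = 0.30
    per_woman_saving: float = 149.0

    def __post_init__(self):
        if self.annual_births < 0:
            raise ValueError("annual births must be nonnegative")
        for f in (self.p_suspected, self.p_preterm_presentation):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def scale_to_population(inputs: ScalingInputs) -> tuple[int, float]:
    """Eligible women per year and the annual saving.

    The eligible count is rounded to the nearest woman before
    multiplying by the per-woman saving.
    """
    eligible = round(
        inputs.annual_births * inputs.p_suspected * inputs.p_preterm_presentation
    )
    return int(eligible), float(eligible * inputs.per_woman_saving)


def proportion_pct(events: int, n: int, digits: int = 1) -> float:
    """Percentage at the printed precision, e.g. 24/447 -> 5.4."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * events / n, digits)


def format_gbp(value: float) -> str:
    """Whole-pound display with the sign ahead of the currency symbol."""
    sign = "-" if value < 0 else ""
    return f"{sign}£{round(abs(value)):,.0f}"


# ---------------------------------------------------------------------------
# table shaping
# ---------------------------------------------------------------------------


def _statistic_rows(result: PSAResult, cat_idx: int) -> dict[str, list[float]]:
    cell = result.cell_diff[:, cat_idx, :]  # (n_iter, 9)
    actual = cell.mean(axis=0)
    if result.weights.ndim == 1:
        weighted = actual * result.weights
    else:
        # per-arm weighting has no exact per-cell decomposition of the
        # weighted difference; report the pooled-style product per arm mix
        weighted = actual * result.weights.mean(axis=1)
    row_total = result.weighted_by_category[:, cat_idx]
    return {
        "Actual": list(actual) + [float(actual.sum())],
        "Weighted": list(weighted) + [float(row_total.mean())],
        "Percentage<0": [prob_cost_saving(cell[:, j]) * 100 for j in range(cell.shape[1])]
        + [prob_cost_saving(row_total) * 100],
    }


def _group_rows(result: PSAResult, group: str, per_woman: np.ndarray) -> dict:
    cell = result.group_cell[group]
    actual = cell.mean(axis=0)
    if result.weights.ndim == 1:
        weighted = actual * result.weights
    else:
        weighted = actual * result.weights.mean(axis=1)
    return {
        "Actual": list(actual) + [float(actual.sum())],
        "Weighted": list(weighted) + [float(per_woman.mean())],
        "Percentage<0": [prob_cost_saving(cell[:, j]) * 100 for j in range(cell.shape[1])]
        + [prob_cost_saving(per_woman) * 100],
    }


def _shape_table(blocks: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    columns = list(SUBGROUP_LABELS) + ["Total"]
    index = pd.MultiIndex.from_tuples(
        [(res, stat) for res, stats_ in blocks.items() for stat in stats_],
        names=["resource_use", "statistic"],
    )
    data = [blocks[res][stat] for res, stat in index]
    return pd.DataFrame(data, index=index, columns=columns)


def table_maternal(result: PSAResult) -> pd.DataFrame:
    """Maternal cost differences per patient (revealed minus usual)."""
    blocks = {
        cat: _statistic_rows(result, CATEGORIES.index(cat))
        for cat in MATERNAL_CATEGORIES
    }
    blocks["Total Maternal"] = _group_rows(result, "maternal", result.maternal)
    return _shape_table(blocks)


def table_infant_combined(result: PSAResult) -> pd.DataFrame:
    """Infant and combined cost differences per patient."""
    blocks = {
        cat: _statistic_rows(result, CATEGORIES.index(cat))
        for cat in INFANT_CATEGORIES
    }
    blocks["Total Infant"] = _group_rows(result, "infant", result.infant)
    blocks["Total Maternal & Infant"] = _group_rows(result, "combined", result.combined)
    return _shape_table(blocks)


# ---------------------------------------------------------------------------
# file outputs
# ---------------------------------------------------------------------------


def render_outputs(
    result: PSAResult,
    out_dir,
    scaling: ScalingInputs | None = None,
    extra_metadata: dict | None = None,
) -> list[Path]:
    """Write all publication-shaped artifacts; idempotent for a fixed
    result (same bytes on every call)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    t1 = table_maternal(result)
    path = out / "table1_maternal_costs.csv"
    t1.to_csv(path)
    written.append(path)

    t2 = table_infant_combined(result)
    path = out / "table2_infant_combined_costs.csv"
    t2.to_csv(path)
    written.append(path)

    path = out / "table3_test_price_sweep.csv"
    result.sweep.to_csv(path, index=False)
    written.append(path)

    path = out / "ceac.csv"
    result.ceac_points.to_csv(path, index=False)
    written.append(path)

    if scaling is None:
        saving = -result.mean_savings["combined_with_test"]
        scaling = ScalingInputs(per_woman_saving=saving)
    eligible, annual_saving = scale_to_population(scaling)
    path = out / "national_scaling.json"
    path.write_text(
        json.dumps(
            {
                "annual_births": scaling.annual_births,
                "p_suspected": scaling.p_suspected,
                "p_preterm_presentation": scaling.p_preterm_presentation,
                "per_woman_saving_gbp": scaling.per_woman_saving,
                "eligible_women": eligible,
                "annual_saving_gbp": annual_saving,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    written.append(path)

    meta = {
        "package_version": __version__,
        "seed": result.config.seed,
        "n_iterations": result.config.n_iterations,
        "test_cost": result.config.test_cost,
        "weights_mode": result.config.weights_mode,
        "probabilities_cost_saving": result.probabilities,
        "mean_weighted_differences_gbp": result.mean_savings,
        "mean_events_avoided_per_1000": float(
            result.events_avoided_per_1000.mean()
        ),
        "dominant": result.dominant,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    path = out / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
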