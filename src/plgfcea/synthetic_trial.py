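"""Synthetic stepped-wedge trial generator.

Emulates the data structure of a multicentre stepped-wedge
cluster-randomised trial of revealed placental growth factor (PlGF)
testing for suspected pre-eclampsia: eleven maternity units of varying
size cross sequentially from usual care to revealed testing every
6-week step; each enrolled woman carries a PlGF band (>100, 12-100,
<12 pg/ml), a final diagnosis (normal, GH/CHT/SGA, pre-eclampsia),
zero-inflated over-dispersed resource-use quantities with a shared
centre random effect and a linear secular trend, a delivery mode, and a
binomial severe-adverse-event flag.

Resource quantities follow a hurdle model: a Bernoulli "any use" part
with probability ``logit⁻¹(logit(p) + u_c + β_t·step)`` and, given use,
a zero-truncated negative binomial whose untruncated location is
calibrated so the truncated mean equals the configured positive-part
mean ``mu``. The Poisson hurdle is the large-``k`` limit of the same
parameterisation.

All randomness flows from one ``numpy`` generator; identical
``(params, seed)`` give byte-identical datasets.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import expit, logit

from .schema import (
    ARMS,
    CATEGORIES,
    DELIVERY_MODES,
    DIAGNOSES,
    PLGF_BANDS,
    RECORD_COLUMNS,
    SUBGROUPS,
)

__all__ = [
    "Design",
    "GeneratorParams",
    "build_design",
    "sample_women",
    "draw_resource_use",
    "draw_adverse_event",
    "simulate_trial",
    "truncated_nb_base_mean",
    "truncated_nb_mean",
    "load_config",
    "write_records",
    "read_records",
]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Design:
    """Stepped-wedge layout: which cluster is on which arm at each step.

    Steps are indexed ``0 .. n_steps - 1``; all clusters deliver usual
    care at step 0 and all deliver the intervention at the final step.
    The cluster in position ``j`` of ``crossover_order`` switches at step
    ``j + 1`` and the intervention indicator is monotone in step.
    """

    clusters: tuple[int, ...]
    weights: tuple[float, ...]
    n_steps: int
    crossover_order: tuple[int, ...]
    step_of_crossover: dict[int, int] = field(repr=False)

    def arm(self, cluster: int, step: int) -> str:
        return "revealed" if step >= self.step_of_crossover[cluster] else "usual"

    def validate(self) -> None:
        if sorted(self.crossover_order) != sorted(self.clusters):
            raise ValueError("crossover_order must be a permutation of clusters")
        for c in self.clusters:
            if not 1 <= self.step_of_crossover[c] <= self.n_steps - 1:
                raise ValueError("crossover steps must lie strictly inside the trial")
        if any(self.arm(c, 0) != "usual" for c in self.clusters):
            raise ValueError("all clusters must start under usual care")
        if any(self.arm(c, self.n_steps - 1) != "revealed" for c in self.clusters):
            raise ValueError("all clusters must end on the intervention")


def build_design(
    n_clusters: int,
    n_steps: int,
    seed: int | np.random.SeedSequence,
    weights: Sequence[float] | None = None,
) -> Design:
    """Randomise the crossover order of ``n_clusters`` units over ``n_steps``.

    Requires ``n_steps >= n_clusters + 1`` so that every cluster both
    starts under usual care (step 0) and has crossed over before the
    final step.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if n_steps < n_clusters + 1:
        raise ValueError(
            f"n_steps={n_steps} too small: a stepped wedge with {n_clusters} "
            f"clusters needs n_steps >= n_clusters + 1 = {n_clusters + 1} so "
            "every cluster crosses over after step 0 and before the end"
        )
    if weights is None:
        weights = [1.0] * n_clusters
    if len(weights) != n_clusters or any(w <= 0 for w in weights):
        raise ValueError("weights must be positive, one per cluster")
    rng = np.random.default_rng(seed)
    order = tuple(int(c) for c in rng.permutation(n_clusters))
    step_of = {c: j + 1 for j, c in enumerate(order)}
    design = Design(
        clusters=tuple(range(n_clusters)),
        weights=tuple(float(w) for w in weights),
        n_steps=int(n_steps),
        crossover_order=order,
        step_of_crossover=step_of,
    )
    design.validate()
    return design


# ---------------------------------------------------------------------------
# generator parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HurdleParams:
    """Hurdle-model cell parameters: use probability, positive mean, dispersion."""

    p: float
    mu_pos: float
    k: float

    def validate(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"use probability {self.p} outside [0, 1]")
        if self.p > 0 and not self.mu_pos > 1.0:
            raise ValueError(
                f"positive-part mean {self.mu_pos} must exceed 1: the "
                "zero-truncated count distribution has support {1, 2, ...}"
            )
        if not self.k > 0:
            raise ValueError("dispersion k must be positive")


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameter set for one simulated trial.

    ``hurdle`` maps ``(category, plgf_band, diagnosis, arm)`` to the
    cell's :class:`HurdleParams`; ``subgroup_probs`` maps each arm to a
    9-vector over the PlGF x diagnosis cells; ``adverse_rates`` holds
    per-arm ``(events, n)`` counts whose ratio is the Bernoulli rate.
    """

    hurdle: Mapping[tuple[str, str, str, str], HurdleParams]
    subgroup_probs: Mapping[str, Mapping[tuple[str, str], float]]
    adverse_rates: Mapping[str, tuple[int, int]]
    n_per_arm: Mapping[str, int]
    sigma_c: float
    beta_t: float
    delivery_probs: Mapping[str, float]

    def validate(self) -> None:
        for key in ((c, b, d, a) for c in CATEGORIES for b, d in SUBGROUPS for a in ARMS):
            if key not in self.hurdle:
                raise ValueError(f"missing hurdle parameters for {key}")
            self.hurdle[key].validate()
        for arm in ARMS:
            probs = self.subgroup_probs[arm]
            total = sum(probs[cell] for cell in SUBGROUPS)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"subgroup probabilities for {arm} sum to {total}")
            if any(probs[cell] < 0 for cell in SUBGROUPS):
                raise ValueError("subgroup probabilities must be nonnegative")
            r, n = self.adverse_rates[arm]
            if not 0 <= r <= n:
                raise ValueError(f"adverse-event counts {r}/{n} invalid")
        if self.sigma_c < 0:
            raise ValueError("sigma_c must be nonnegative")
        if abs(sum(self.delivery_probs[m] for m in DELIVERY_MODES) - 1.0) > 1e-9:
            raise ValueError("delivery-mode probabilities must sum to 1")

    def adverse_rate(self, arm: str) -> float:
        r, n = self.adverse_rates[arm]
        return r / n

    @classmethod
    def from_config(cls, config: Mapping) -> "GeneratorParams":
        """Expand a compact configuration (base values plus multiplicative
        diagnosis / band / arm modifiers) into the per-cell grid."""
        hurdle: dict[tuple[str, str, str, str], HurdleParams] = {}
        for cat in CATEGORIES:
            spec = config["resource_use"][cat]
            base = spec["base"]
            for band, dx in SUBGROUPS:
                for arm in ARMS:
                    odds = base["p"] / (1.0 - base["p"]) if base["p"] < 1 else np.inf
                    odds *= spec.get("dx_odds", {}).get(dx, 1.0)
                    odds *= spec.get("plgf_odds", {}).get(band, 1.0)
                    mu = base["mu"]
                    mu *= spec.get("dx_mu", {}).get(dx, 1.0)
                    mu *= spec.get("plgf_mu", {}).get(band, 1.0)
                    if arm == "revealed":
                        odds *= spec.get("revealed_odds", {}).get(band, 1.0)
                        mu *= spec.get("revealed_mu", {}).get(band, 1.0)
                    p = odds / (1.0 + odds) if np.isfinite(odds) else 1.0
                    hurdle[(cat, band, dx, arm)] = HurdleParams(p=p, mu_pos=mu, k=base["k"])

        marg = config["subgroups"]["plgf_marginals"]
        cond = config["subgroups"]["diagnosis_given_plgf"]
        cell = {(b, d): float(marg[b]) * float(cond[b][d]) for b, d in SUBGROUPS}
        total = sum(cell.values())
        cell = {k: v / total for k, v in cell.items()}
        subgroup_probs = {arm: dict(cell) for arm in ARMS}

        ae = config["adverse_events"]
        params = cls(
            hurdle=hurdle,
            subgroup_probs=subgroup_probs,
            adverse_rates={arm: (int(ae[arm]["events"]), int(ae[arm]["n"])) for arm in ARMS},
            n_per_arm={arm: int(config["enrolment"][arm]) for arm in ARMS},
            sigma_c=float(config["cluster_effects"]["sigma_c"]),
            beta_t=float(config["cluster_effects"]["beta_t"]),
            delivery_probs={m: float(config["delivery"]["mode_probs"][m]) for m in DELIVERY_MODES},
        )
        params.validate()
        return params


def load_config(path: str | None = None) -> dict:
    """Load a run configuration; ``None`` loads the packaged default."""
    if path is None:
        ref = importlib.resources.files("plgfcea.data").joinpath("default_trial.yaml")
        return yaml.safe_load(ref.read_text())
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# zero-truncated negative binomial helpers
# ---------------------------------------------------------------------------


def _nb_p0(mu, k):
    """P(Y = 0) of the untruncated NB(mean mu, dispersion k)."""
    mu = np.asarray(mu, dtype=float)
    k = np.asarray(k, dtype=float)
    return np.exp(k * (np.log(k) - np.log(k + mu)))


def truncated_nb_mean(mu, k):
    """Mean of the zero-truncated NB given untruncated location ``mu``."""
    mu = np.asarray(mu, dtype=float)
    return mu / (1.0 - _nb_p0(mu, k))


def truncated_nb_base_mean(target_mean: float, k: float) -> float:
    """Untruncated NB location whose zero-truncated mean is ``target_mean``.

    The truncated mean is strictly increasing in the location and tends
    to 1 as the location tends to 0, so a solution exists iff
    ``target_mean > 1``.
    """
    if not target_mean > 1.0:
        raise ValueError("zero-truncated mean must exceed 1")
    f = lambda m: truncated_nb_mean(m, k) - target_mean
    lo, hi = 1e-12, target_mean
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def _draw_zt_nb(rng: np.random.Generator, mu, k) -> np.ndarray:
    """Zero-truncated NB draws by inverse CDF restricted to {1, 2, ...}."""
    mu = np.asarray(mu, dtype=float)
    k = np.asarray(k, dtype=float)
    p = k / (k + mu)  # scipy's nbinom success probability
    p0 = _nb_p0(mu, k)
    u = p0 + (1.0 - p0) * rng.random(mu.shape)
    # guard against u == 1 rounding past the support
    u = np.minimum(u, 1.0 - 1e-14)
    return stats.nbinom.ppf(u, k, p).astype(int)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_women(
    design: Design, params: GeneratorParams, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """Assign design coordinates (cluster, step, arm) and a subgroup to
    every woman; per-arm totals are the configured enrolment counts."""
    params.validate()
    rng = np.random.default_rng(seed)
    frames = []
    weights = np.asarray(design.weights, dtype=float)
    cells = [
        (c, s)
        for c in design.clusters
        for s in range(design.n_steps)
    ]
    cell_arm = np.array([design.arm(c, s) for c, s in cells])
    cell_w = np.array([weights[c] for c, s in cells], dtype=float)
    for arm in ARMS:
        n = params.n_per_arm[arm]
        mask = cell_arm == arm
        idx = np.flatnonzero(mask)
        pw = cell_w[idx] / cell_w[idx].sum()
        chosen = rng.choice(idx, size=n, p=pw)
        cluster = np.array([cells[i][0] for i in chosen])
        step = np.array([cells[i][1] for i in chosen])
        probs = np.array([params.subgroup_probs[arm][cell] for cell in SUBGROUPS])
        sub_idx = rng.choice(len(SUBGROUPS), size=n, p=probs)
        frames.append(
            pd.DataFrame(
                {
                    "cluster": cluster,
                    "step": step,
                    "arm": arm,
                    "plgf_category": [SUBGROUPS[i][0] for i in sub_idx],
                    "diagnosis": [SUBGROUPS[i][1] for i in sub_idx],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", np.arange(len(df)))
    return df


def _cell_grids(params: GeneratorParams, category: str):
    """(p, base_mu, k) lookup arrays indexed by (band, dx, arm)."""
    p = {}
    base = {}
    k = {}
    for band, dx in SUBGROUPS:
        for arm in ARMS:
            h = params.hurdle[(category, band, dx, arm)]
            p[(band, dx, arm)] = h.p
            base[(band, dx, arm)] = (
                truncated_nb_base_mean(h.mu_pos, h.k) if h.p > 0 else np.nan
            )
            k[(band, dx, arm)] = h.k
    return p, base, k


def draw_resource_use(
    record: Mapping,
    params: GeneratorParams,
    rng: np.random.Generator,
    u_c: float = 0.0,
) -> dict[str, int]:
    """Draw the resource-use map for one woman.

    ``u_c`` is the woman's cluster random intercept, drawn once per
    cluster by the caller; the linear predictor of both hurdle parts is
    shifted by ``u_c + beta_t * step`` on the link scale.
    """
    key = (record["plgf_category"], record["diagnosis"], record["arm"])
    shift = u_c + params.beta_t * record["step"]
    if not np.isfinite(shift):
        raise ValueError("non-finite linear predictor in resource-use draw")
    out: dict[str, int] = {}
    for cat in CATEGORIES:
        h = params.hurdle[(cat, *key)]
        if h.p <= 0.0:
            out[cat] = 0
            continue
        p_use = expit(logit(min(h.p, 1 - 1e-12)) + shift)
        if rng.random() >= p_use:
            out[cat] = 0
            continue
        base = truncated_nb_base_mean(h.mu_pos, h.k)
        mu = np.exp(np.log(base) + shift)
        out[cat] = int(_draw_zt_nb(rng, np.array([mu]), h.k)[0])
    return out


def draw_adverse_event(record, params: GeneratorParams, rng: np.random.Generator):
    """Bernoulli severe-adverse-event flag(s) at the arm's configured rate.

    Accepts a single record mapping (returns ``bool``) or a records
    DataFrame (returns an integer array).
    """
    if isinstance(record, pd.DataFrame):
        rates = record["arm"].map({arm: params.adverse_rate(arm) for arm in ARMS})
        return (rng.random(len(record)) < rates.to_numpy()).astype(int)
    return bool(rng.random() < params.adverse_rate(record["arm"]))


def simulate_trial(
    config: Mapping | None = None,
    seed: int | np.random.SeedSequence | None = None,
    params: GeneratorParams | None = None,
    design: Design | None = None,
) -> pd.DataFrame:
    """Generate one full trial dataset (one row per woman).

    Resource-use draws are vectorised per category over the whole cohort
    but follow exactly the per-record hurdle model of
    :func:`draw_resource_use`.
    """
    if config is None:
        config = load_config()
    if params is None:
        params = GeneratorParams.from_config(config)
    if seed is None:
        seed = int(config.get("seed", 0))
    root = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    s_design, s_women, s_cluster, s_use, s_extra = root.spawn(5)

    if design is None:
        dcfg = config["design"]
        design = build_design(
            int(dcfg["n_clusters"]),
            int(dcfg["n_steps"]),
            s_design,
            weights=dcfg.get("cluster_weights"),
        )
    df = sample_women(design, params, s_women)

    rng_c = np.random.default_rng(s_cluster)
    u = rng_c.normal(0.0, params.sigma_c, size=len(design.clusters))
    shift = u[df["cluster"].to_numpy()] + params.beta_t * df["step"].to_numpy()

    rng = np.random.default_rng(s_use)
    keys = list(zip(df["plgf_category"], df["diagnosis"], df["arm"]))
    for cat in CATEGORIES:
        p_grid, base_grid, k_grid = _cell_grids(params, cat)
        p0 = np.array([p_grid[key] for key in keys])
        base = np.array([base_grid[key] for key in keys])
        k = np.array([k_grid[key] for key in keys])
        with np.errstate(divide="ignore"):
            eta_p = np.where(p0 >= 1.0, np.inf, logit(np.clip(p0, 1e-12, 1 - 1e-12)))
        p_use = expit(eta_p + shift)
        p_use = np.where(p0 <= 0.0, 0.0, p_use)
        use = rng.random(len(df)) < p_use
        counts = np.zeros(len(df), dtype=int)
        if use.any():
            mu = np.exp(np.log(base[use]) + shift[use])
            counts[use] = _draw_zt_nb(rng, mu, k[use])
        df[cat] = counts
    df["infant_icu_hdu_admitted"] = (df["infant_icu_hdu"] > 0).astype(int)

    rng_x = np.random.default_rng(s_extra)
    modes = np.array(DELIVERY_MODES)
    mode_p = np.array([params.delivery_probs[m] for m in DELIVERY_MODES])
    df["delivery_mode"] = rng_x.choice(modes, size=len(df), p=mode_p)
    df["adverse_event"] = draw_adverse_event(df, params, rng_x)
    return df[list(RECORD_COLUMNS)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    return df
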