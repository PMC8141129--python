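"""Probabilistic sensitivity analysis.

Each draw samples every distribution-backed scalar parameter independently
from its PSA spec (gamma for costs, lognormal for relative risks, beta for
probabilities), re-evaluates every screening strategy at the drawn parameter
set, and the collection of per-draw (cost, QALY) pairs is summarized as an
incremental scatter and as cost-effectiveness acceptability curves (the
fraction of draws in which each strategy maximizes net monetary benefit at
each willingness-to-pay value).

Two evaluation modes are available: ``cohort`` (deterministic expectation per
draw; isolates parameter uncertainty) and ``microsim`` (first-order Monte
Carlo with ``n_individuals`` per draw; mirrors the 1000-individuals-by-
1000-iterations design of the reference analysis, conflating individual-level
and parameter-level noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DistributionError, ValidationError
from .microsim import run_cohort_expectation, run_microsim
from .parameters import PSA_PARAMETERS, DistributionSpec, ModelConfig
from .life_table import LifeTable

__all__ = ["PSADraw", "PSAResult", "AcceptabilityCurve",
           "sample_spec", "sample_draw", "run_psa", "acceptability", "psa_summary"]

_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class PSADraw:
    index: int
    values: dict[str, float]


@dataclass(frozen=True)
class PSAResult:
    """Rectangular per-draw per-strategy outcomes.

    ``costs`` and ``qalys`` have shape (n_draws, n_strategies), columns
    ordered as ``strategy_labels``.
    """

    strategy_labels: tuple[str, ...]
    costs: np.ndarray
    qalys: np.ndarray
    seed: int
    param_draws: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.costs.shape != self.qalys.shape or self.costs.shape[1] != len(self.strategy_labels):
            raise ValidationError("costs/qalys must be (n_draws, n_strategies)")

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def column(self, label: str) -> int:
        try:
            return self.strategy_labels.index(label)
        except ValueError:
            raise KeyError(f"no strategy labelled {label!r}") from None

    def scatter_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_draws):
            for j, label in enumerate(self.strategy_labels):
                rows.append({"draw": i, "strategy": label,
                             "cost": self.costs[i, j], "qaly": self.qalys[i, j]})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AcceptabilityCurve:
    wtp_grid: np.ndarray
    strategy_labels: tuple[str, ...]
    probabilities: np.ndarray  # (n_wtp, n_strategies)

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, w in enumerate(self.wtp_grid):
            for j, label in enumerate(self.strategy_labels):
                rows.append({"wtp": float(w), "strategy": label,
                             "probability": self.probabilities[i, j]})
        return pd.DataFrame(rows)


def sample_spec(spec: DistributionSpec, rng: np.random.Generator,
                domain: tuple[float, float] = (0.0, np.inf)) -> float:
    """One draw from a PSA spec, rejection-sampled into ``domain``."""
    lo, hi = domain
    for _ in range(_MAX_REJECTIONS):
        if spec.family == "fixed":
            x = spec.point_estimate
        elif spec.family == "gamma":
            x = rng.gamma(spec.params["shape"], spec.params["scale"])
        elif spec.family == "lognormal":
            x = float(np.exp(spec.params["log_mean"]
                             + spec.params["log_sd"] * rng.standard_normal()))
        elif spec.family == "beta":
            x = rng.beta(spec.params["alpha"], spec.params["beta"])
        else:  # pragma: no cover - DistributionSpec already rejects this
            raise DistributionError(f"unsupported family {spec.family!r}")
        if lo <= x <= hi:
            return float(x)
        if spec.family == "fixed":
            break
    raise DistributionError(
        f"{_MAX_REJECTIONS} consecutive draws of {spec.family} fell outside {domain}")


def sample_draw(cfg: ModelConfig, rng: np.random.Generator, index: int = 0) -> PSADraw:
    """Sample every PSA parameter independently (alphabetical order, so the
    draw is reproducible regardless of config-file key order)."""
    if not cfg.psa:
        raise ValidationError("config has no PSA distributions")
    values = {}
    for name in sorted(cfg.psa):
        domain = PSA_PARAMETERS[name][1]
        values[name] = sample_spec(cfg.psa[name], rng, domain)
    return PSADraw(index=index, values=values)


def run_psa(cfg: ModelConfig, lt: LifeTable, n_draws: int = 1000,
            n_individuals: int = 1000, seed: int = 0,
            mode: str = "cohort") -> PSAResult:
    """Sample ``n_draws`` parameter sets and evaluate every strategy at each.

    ``mode='cohort'`` uses the deterministic expectation (default);
    ``mode='microsim'`` runs ``n_individuals`` per strategy per draw with a
    sub-seed derived from ``seed`` and the draw/strategy index.
    """
    if n_draws < 1 or n_individuals < 1:
        raise ValidationError("n_draws and n_individuals must be >= 1")
    if mode not in ("cohort", "microsim"):
        raise ValidationError(f"unknown evaluation mode {mode!r}")
    rng = np.random.default_rng(seed)
    labels = tuple(tc.label for tc in cfg.strategies)
    costs = np.empty((n_draws, len(labels)))
    qalys = np.empty((n_draws, len(labels)))
    records = []
    for i in range(n_draws):
        draw = sample_draw(cfg, rng, index=i)
        records.append(draw.values)
        cfg_i = cfg.with_values(draw.values)
        for j, tc in enumerate(cfg_i.strategies):
            if mode == "cohort":
                res = run_cohort_expectation(cfg_i, tc, lt)
            else:
                sub = int(np.random.SeedSequence(seed, spawn_key=(i, j)).generate_state(1)[0])
                res = run_microsim(cfg_i, tc, lt, n=n_individuals, seed=sub & 0x7FFFFFFF)
            costs[i, j] = res.mean_cost
            qalys[i, j] = res.mean_qaly
    return PSAResult(strategy_labels=labels, costs=costs, qalys=qalys, seed=seed,
                     param_draws=pd.DataFrame(records))


def acceptability(res: PSAResult, wtp_grid: np.ndarray) -> AcceptabilityCurve:
    """Cost-effectiveness acceptability curves.

    At each WTP value, each draw's winner is the strategy with maximal net
    monetary benefit; exact ties share the win equally.  Probabilities sum
    to 1 at every WTP.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0 or np.any(np.diff(wtp_grid) < 0):
        raise ValidationError("wtp_grid must be non-empty and sorted")
    n_draws, n_strat = res.costs.shape
    probs = np.zeros((wtp_grid.size, n_strat))
    for i, w in enumerate(wtp_grid):
        nmb_matrix = w * res.qalys - res.costs
        best = nmb_matrix.max(axis=1, keepdims=True)
        winners = nmb_matrix == best
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0) / n_draws
    return AcceptabilityCurve(wtp_grid=wtp_grid, strategy_labels=res.strategy_labels,
                              probabilities=probs)


def psa_summary(res: PSAResult, comparator: str, target: str) -> dict[str, float]:
    """Incremental summary of ``target`` vs ``comparator``.

    Reports the mean per-draw cost and QALY deltas, the ICER of the mean
    deltas (never the mean of per-draw ratios, which is unstable), and
    2.5/97.5 empirical percentile intervals of the per-draw deltas.
    """
    jc, jt = res.column(comparator), res.column(target)
    d_cost = res.costs[:, jt] - res.costs[:, jc]
    d_qaly = res.qalys[:, jt] - res.qalys[:, jc]
    mean_dc, mean_dq = float(d_cost.mean()), float(d_qaly.mean())
    icer = mean_dc / mean_dq if mean_dq != 0 else None
    lo_c, hi_c = np.quantile(d_cost, [0.025, 0.975])
    lo_q, hi_q = np.quantile(d_qaly, [0.025, 0.975])
    return {"mean_delta_cost": mean_dc, "mean_delta_qaly": mean_dq, "icer": icer,
            "delta_cost_ci": (float(lo_c), float(hi_c)),
            "delta_qaly_ci": (float(lo_q), float(hi_q))}
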