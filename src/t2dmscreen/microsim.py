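"""First-order Monte Carlo engine for the screening state-transition model.

Individuals enter healthy at an age drawn from their stratum's band and move
through annual cycles until death or the terminal age.  Each cycle applies,
in order:

1. **screening** (only in cycles where ``t mod interval_years == 0`` and only
   for states still in the screening pool): an undiagnosed case is detected
   with probability *sensitivity*; a healthy person is flagged false-positive
   with probability *1 - specificity*; an existing false positive reverts to
   healthy on a true-negative result.  The test fee is charged per screen.
2. **disease transition**: incidence (healthy/false-positive -> undiagnosed
   diabetes), complication (undiagnosed at the untreated rate, treated at the
   hazard-scale-reduced rate; the complication state is absorbing and implies
   diagnosis), then death at the life-table probability scaled by the state's
   mortality relative risk.
3. **accrual** of the post-transition state's annual cost and utility,
   discounted by ``(1+d)^-t``.  No half-cycle correction is applied.

Two evaluators share these dynamics: :func:`run_microsim` (vectorized
individual-level simulation, the study design) and
:func:`run_cohort_expectation` (exact propagation of the state distribution,
used as the deterministic oracle and as the fast PSA mode).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DomainError, ValidationError
from .life_table import LifeTable, adjusted_mortality
from .parameters import ModelConfig, RiskSet, TestCharacteristics

__all__ = [
    "HealthState",
    "StrategyResult",
    "discount_factor",
    "accrue",
    "screening_event",
    "annual_transition",
    "simulate_individual",
    "run_microsim",
    "run_cohort_expectation",
]


class HealthState(enum.IntEnum):
    HEALTHY = 0
    FALSE_POSITIVE = 1
    UNDETECTED_T2DM = 2
    TREATED_T2DM = 3
    COMPLICATION = 4
    DEAD = 5


_SCREENABLE = (HealthState.HEALTHY, HealthState.FALSE_POSITIVE, HealthState.UNDETECTED_T2DM)


@dataclass(frozen=True)
class StrategyResult:
    """Mean discounted cost (USD) and QALYs for one strategy in one stratum.

    ``n == 0`` marks an analytic (cohort-expectation) result with zero
    standard errors.
    """

    strategy_label: str
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.mean_cost < 0 or self.mean_qaly < 0:
            raise ValidationError("mean cost and QALY must be >= 0")
        if self.se_cost < 0 or self.se_qaly < 0:
            raise ValidationError("standard errors must be >= 0")


def discount_factor(t: int, d: float) -> float:
    """Present-value multiplier ``(1+d)^-t`` for cycle ``t``."""
    if t < 0 or d < 0:
        raise DomainError("t and d must be >= 0")
    return (1.0 + d) ** (-t)


def accrue(state: HealthState, cfg: ModelConfig) -> tuple[float, float]:
    """Annual (cost, utility) accrued while occupying ``state``."""
    c, u = cfg.costs, cfg.utilities
    table = {
        HealthState.HEALTHY: (0.0, u.healthy),
        HealthState.FALSE_POSITIVE: (c.fp_annual, u.healthy),
        HealthState.UNDETECTED_T2DM: (0.0, u.t2dm_no_comp),
        HealthState.TREATED_T2DM: (c.tx_no_comp_annual, u.t2dm_no_comp),
        HealthState.COMPLICATION: (c.tx_comp_annual, u.t2dm_comp),
        HealthState.DEAD: (0.0, 0.0),
    }
    return table[HealthState(state)]


def screening_event(state: HealthState, tc: TestCharacteristics,
                    rng: np.random.Generator) -> HealthState:
    """One HbA1c test applied to a member of the screening pool."""
    state = HealthState(state)
    if state not in _SCREENABLE:
        raise ContractError(f"screening_event called on {state.name}")
    u = rng.random()
    if state is HealthState.UNDETECTED_T2DM:
        return HealthState.TREATED_T2DM if u < tc.sensitivity else state
    if state is HealthState.HEALTHY:
        return HealthState.FALSE_POSITIVE if u < 1.0 - tc.specificity else state
    # FALSE_POSITIVE: re-tested as a healthy person; a true negative clears the label
    return HealthState.HEALTHY if u < tc.specificity else state


def annual_transition(state: HealthState, risks: RiskSet, lt: LifeTable, age: int,
                      rng: np.random.Generator) -> HealthState:
    """One cycle of disease dynamics: incidence, complication, then death."""
    state = HealthState(state)
    if state is HealthState.DEAD:
        raise ContractError("annual_transition called on DEAD")
    if risks.annual_incidence is None:
        raise ValidationError("annual_incidence is unset; supply a stratum-specific value")
    if state in (HealthState.HEALTHY, HealthState.FALSE_POSITIVE):
        if rng.random() < risks.annual_incidence:
            state = HealthState.UNDETECTED_T2DM
    if state is HealthState.UNDETECTED_T2DM:
        if rng.random() < risks.annual_comp_rate:
            state = HealthState.COMPLICATION
    elif state is HealthState.TREATED_T2DM:
        p = adjusted_mortality(risks.annual_comp_rate, risks.rr_comp_treated)
        if rng.random() < p:
            state = HealthState.COMPLICATION
    qx = float(lt.qx_at(age))
    rr = _mortality_rr(risks)[state]
    if rng.random() < adjusted_mortality(qx, rr):
        state = HealthState.DEAD
    return state


def _mortality_rr(risks: RiskSet) -> np.ndarray:
    return np.array([1.0, 1.0, risks.rr_mort_untreated, risks.rr_mort_treated,
                     risks.rr_mort_comp, 1.0])


def _accrual_arrays(cfg: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    c, u = cfg.costs, cfg.utilities
    cost = np.array([0.0, c.fp_annual, 0.0, c.tx_no_comp_annual, c.tx_comp_annual, 0.0])
    util = np.array([u.healthy, u.healthy, u.t2dm_no_comp, u.t2dm_no_comp, u.t2dm_comp, 0.0])
    return cost, util


def _check_inputs(cfg: ModelConfig, strategy: TestCharacteristics, lt: LifeTable) -> None:
    if strategy not in cfg.strategies:
        raise ContractError(f"strategy {strategy.label!r} is not one of the config's strategies")
    if cfg.risks.annual_incidence is None:
        raise ValidationError("annual_incidence is unset; supply a stratum-specific value")
    lo = cfg.settings.entry_age if cfg.settings.entry_age is not None else cfg.stratum.age_low
    if lo < lt.min_age or cfg.settings.max_age - 1 > lt.max_age:
        raise DomainError("life table does not cover the simulated age range")


def simulate_individual(cfg: ModelConfig, strategy: TestCharacteristics, lt: LifeTable,
                        rng: np.random.Generator, entry_age: int,
                        trace: list | None = None) -> dict[str, float]:
    """Simulate one individual; optionally append per-cycle trace records.

    Scalar reference path built directly on :func:`screening_event` and
    :func:`annual_transition`; :func:`run_microsim` is the vectorized
    equivalent of this loop.
    """
    if not (cfg.stratum.age_low <= entry_age <= cfg.stratum.age_high):
        raise DomainError(f"entry_age {entry_age} outside the stratum band")
    d = cfg.settings.discount_rate
    state = HealthState.HEALTHY
    age = entry_age
    cost = qaly = 0.0
    t = 0
    while state is not HealthState.DEAD and age < cfg.settings.max_age:
        df = discount_factor(t, d)
        if t % strategy.interval_years == 0 and state in _SCREENABLE:
            state = screening_event(state, strategy, rng)
            cost += cfg.costs.screening_cost * df
        state = annual_transition(state, cfg.risks, lt, age, rng)
        c, u = accrue(state, cfg)
        cost += c * df
        qaly += u * df
        if trace is not None:
            trace.append({"cycle": t, "age": age, "state": state.name,
                          "cost": c * df, "utility": u * df})
        age += 1
        t += 1
    return {"discounted_cost": cost, "discounted_qaly": qaly}


def run_microsim(cfg: ModelConfig, strategy: TestCharacteristics, lt: LifeTable,
                 n: int | None = None, seed: int | None = None) -> StrategyResult:
    """Vectorized first-order Monte Carlo over ``n`` independent individuals.

    Identical ``(cfg, strategy, lt, n, seed)`` give bit-identical results:
    all randomness comes from one ``default_rng(seed)`` stream with a fixed
    draw order (entry ages, then four uniforms per individual per cycle).
    """
    _check_inputs(cfg, strategy, lt)
    s, st, r = cfg.settings, cfg.stratum, cfg.risks
    n = s.cohort_size if n is None else int(n)
    if n < 1:
        raise ValidationError("n must be >= 1")
    seed = s.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    if s.entry_age is not None:
        entry = np.full(n, s.entry_age, dtype=np.int64)
    else:
        entry = rng.integers(st.age_low, st.age_high + 1, size=n)
    age = entry.copy()
    state = np.zeros(n, dtype=np.int8)
    cost = np.zeros(n)
    qaly = np.zeros(n)

    inc = float(r.annual_incidence)
    cr = r.annual_comp_rate
    cr_treated = adjusted_mortality(cr, r.rr_comp_treated)
    rr = _mortality_rr(r)
    cost_by_state, util_by_state = _accrual_arrays(cfg)
    k = strategy.interval_years
    sens, spec = strategy.sensitivity, strategy.specificity

    H, FP, U, T, C, D = (int(x) for x in HealthState)
    max_cycles = int(s.max_age - entry.min())
    for t in range(max_cycles):
        active = (state != D) & (age < s.max_age)
        if not active.any():
            break
        u4 = rng.random((4, n))
        df = (1.0 + s.discount_rate) ** (-t)
        if t % k == 0:
            pool = active & (state <= U)
            cost[pool] += cfg.costs.screening_cost * df
            us = u4[0]
            to_treated = pool & (state == U) & (us < sens)
            to_fp = pool & (state == H) & (us < 1.0 - spec)
            to_healthy = pool & (state == FP) & (us < spec)
            state[to_treated] = T
            state[to_fp] = FP
            state[to_healthy] = H
        new_case = active & ((state == H) | (state == FP)) & (u4[1] < inc)
        state[new_case] = U
        comp = active & (((state == U) & (u4[2] < cr)) | ((state == T) & (u4[2] < cr_treated)))
        state[comp] = C
        qx = lt.qx_at(age)
        p_death = 1.0 - (1.0 - qx) ** rr[state]
        died = active & (u4[3] < p_death)
        state[died] = D
        cost += np.where(active, cost_by_state[state] * df, 0.0)
        qaly += np.where(active, util_by_state[state] * df, 0.0)
        age[active] += 1

    return StrategyResult(
        strategy_label=strategy.label,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n=n,
        seed=int(seed),
    )


def _cohort_single(cfg: ModelConfig, strategy: TestCharacteristics, lt: LifeTable,
                   entry_age: int) -> tuple[float, float]:
    """Exact expected (cost, qaly) for a fixed entry age, by propagating the
    probability mass over the six states with the same event ordering as the
    microsimulation."""
    s, r = cfg.settings, cfg.risks
    inc = float(r.annual_incidence)
    cr = r.annual_comp_rate
    cr_treated = float(adjusted_mortality(cr, r.rr_comp_treated))
    rr = _mortality_rr(r)
    cost_by_state, util_by_state = _accrual_arrays(cfg)
    k = strategy.interval_years
    sens, spec = strategy.sensitivity, strategy.specificity

    h, fp, u, tr, c, dead = 1.0, 0.0, 0.0, 0.0, 0.0, 0.0
    cost = qaly = 0.0
    for t in range(s.max_age - entry_age):
        age = entry_age + t
        df = (1.0 + s.discount_rate) ** (-t)
        if t % k == 0:
            cost += cfg.costs.screening_cost * df * (h + fp + u)
            detected = u * sens
            flagged = h * (1.0 - spec)
            cleared = fp * spec
            u -= detected
            tr += detected
            h = h - flagged + cleared
            fp = fp - cleared + flagged
        new_cases = (h + fp) * inc
        h *= 1.0 - inc
        fp *= 1.0 - inc
        u += new_cases
        from_u = u * cr
        from_t = tr * cr_treated
        u -= from_u
        tr -= from_t
        c += from_u + from_t
        qx = float(lt.qx_at(age))
        live = [h, fp, u, tr, c]
        deaths = [m * (1.0 - (1.0 - qx) ** rr[i]) for i, m in enumerate(live)]
        h, fp, u, tr, c = (m - dd for m, dd in zip(live, deaths))
        dead += sum(deaths)
        total = h + fp + u + tr + c + dead
        if abs(total - 1.0) > 1e-12:
            raise AssertionError(f"probability mass drifted to {total!r} at cycle {t}")
        occ = (h, fp, u, tr, c, 0.0)
        cost += df * sum(m * cost_by_state[i] for i, m in enumerate(occ))
        qaly += df * sum(m * util_by_state[i] for i, m in enumerate(occ))
    return cost, qaly


def run_cohort_expectation(cfg: ModelConfig, strategy: TestCharacteristics,
                           lt: LifeTable) -> StrategyResult:
    """Deterministic expectation of the microsimulation.

    Averages the exact per-entry-age expectations over the entry-age
    distribution (uniform over the stratum band, or the fixed configured
    age).  Returned with ``n=0`` and zero standard errors to mark it
    analytic.
    """
    _check_inputs(cfg, strategy, lt)
    s, st = cfg.settings, cfg.stratum
    if s.entry_age is not None:
        entry_ages = [s.entry_age]
    else:
        entry_ages = list(range(st.age_low, st.age_high + 1))
    results = [_cohort_single(cfg, strategy, lt, a) for a in entry_ages]
    mean_cost = sum(c for c, _ in results) / len(results)
    mean_qaly = sum(q for _, q in results) / len(results)
    return StrategyResult(strategy.label, mean_cost, mean_qaly, 0.0, 0.0, n=0, seed=s.seed)
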