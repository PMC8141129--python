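import numpy as np
import pytest
from hypothesis import settings

from t2dmscreen.life_table import LifeTable
from t2dmscreen.parameters import (CostSet, EconSettings, ModelConfig, RiskSet,
                                   StratumKey, TestCharacteristics, UtilitySet)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def flat_life_table(qx: float, min_age: int = 0, max_age: int = 110) -> LifeTable:
    """Constant annual death probability at every age below the terminal one."""
    q = np.full(max_age - min_age + 1, qx, dtype=float)
    q[-1] = 1.0
    return LifeTable(min_age=min_age, qx=q)


def make_config(*, strategies=None, incidence=0.02, comp_rate=0.014,
                rr_comp_treated=0.79, rr_mort_comp=5.22, rr_mort_untreated=2.61,
                rr_mort_treated=1.0, screening_cost=100.0, tx_no_comp=3500.0,
                tx_comp=8000.0, fp_annual=1400.0, healthy=1.0, t2dm=0.785,
                t2dm_comp=0.638, discount=0.02, entry_age=60, age_low=60,
                age_high=74, max_age=85, seed=0, psa=None) -> ModelConfig:
    """Small, fully specified config for unit tests; entry age fixed by default
    so expectations are easy to reason about."""
    if strategies is None:
        strategies = (TestCharacteristics("annual", 1, 0.0, 1.0),
                      TestCharacteristics("3-year", 3, 0.6, 0.975))
    return ModelConfig(
        stratum=StratumKey(age_low, age_high, "obese"),
        strategies=tuple(strategies),
        costs=CostSet(screening_cost, tx_no_comp, tx_comp, fp_annual),
        utilities=UtilitySet(healthy, t2dm, t2dm_comp),
        risks=RiskSet(incidence, comp_rate, rr_comp_treated, rr_mort_comp,
                      rr_mort_untreated, rr_mort_treated),
        settings=EconSettings(discount_rate=discount, cohort_size=1000,
                              max_age=max_age, seed=seed, entry_age=entry_age),
        psa=psa or {},
    )


def random_toy_config(rng: np.random.Generator) -> ModelConfig:
    """Randomized small config for stochastic/deterministic agreement checks."""
    k2 = int(rng.integers(2, 6))
    strategies = (
        TestCharacteristics("annual", 1, float(rng.uniform(0, 0.1)), float(rng.uniform(0.98, 1.0))),
        TestCharacteristics("longer", k2, float(rng.uniform(0.4, 0.9)), float(rng.uniform(0.95, 1.0))),
    )
    return make_config(
        strategies=strategies,
        incidence=float(rng.uniform(0.005, 0.08)),
        comp_rate=float(rng.uniform(0.005, 0.05)),
        rr_comp_treated=float(rng.uniform(0.5, 1.0)),
        rr_mort_comp=float(rng.uniform(3.0, 6.0)),
        rr_mort_untreated=float(rng.uniform(1.5, 3.0)),
        entry_age=int(rng.integers(60, 70)),
        max_age=int(rng.integers(86, 95)),
        discount=float(rng.choice([0.0, 0.02])),
    )


@pytest.fixture
def toy_lt() -> LifeTable:
    return flat_life_table(0.01)
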