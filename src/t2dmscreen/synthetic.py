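"""Synthetic model inputs.

The published analysis relied on two inputs it never printed: the national
period life table and the stratum-specific annual incidence of type 2
diabetes.  This module generates statistically plausible stand-ins so every
pipeline stage can run and be tested end to end: a Gompertz–Makeham life
table (see :mod:`t2dmscreen.life_table`) and a multiplicative incidence rule
that rises with age band and BMI category, matching the qualitative premise
that diabetes risk increases with both.  All generated values are synthetic
and clearly parameterized; none is a published number.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .life_table import LifeTable, make_gompertz_lifetable, write_life_table
from .parameters import ModelConfig, StratumKey, TestCharacteristics, write_bundle
from .reference import AGE_BANDS, BMI_ORDER, STRATA, reference_preset

__all__ = ["GeneratorSettings", "gen_incidence", "gen_config",
           "gen_bundle", "write_fixture_set"]


@dataclass(frozen=True)
class GeneratorSettings:
    """Knobs of the synthetic-input generator.

    Incidence is ``incidence_base * incidence_age_slope**i * incidence_bmi_slope**j``
    for age-band index i (0..2) and BMI index j (0..3), clipped to [0, 0.5].
    The defaults (0.3%/year base, x1.6 per age band, x1.8 per BMI category)
    are deliberately round, documented values in the range typical of adult
    T2DM incidence; they are not estimates from any cohort.
    """

    seed: int = 0
    incidence_base: float = 0.003
    incidence_age_slope: float = 1.6
    incidence_bmi_slope: float = 1.8
    sens_range: tuple[float, float] = (0.3, 0.9)
    spec_range: tuple[float, float] = (0.97, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.incidence_base <= 1.0):
            raise ValidationError("incidence_base must be in [0,1]")
        if self.incidence_age_slope <= 0 or self.incidence_bmi_slope <= 0:
            raise ValidationError("incidence slopes must be > 0")
        for name in ("sens_range", "spec_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValidationError(f"{name} must satisfy 0 <= lo <= hi <= 1")


def _indices(key: StratumKey) -> tuple[int, int]:
    age_idx = [lo for lo, _ in AGE_BANDS].index(key.age_low)
    bmi_idx = BMI_ORDER.index(key.bmi_category)
    return age_idx, bmi_idx


def gen_incidence(key: StratumKey, gs: GeneratorSettings = GeneratorSettings()) -> float:
    """Synthetic annual T2DM incidence for one stratum (multiplicative in the
    ordinal age-band and BMI indices, clipped to [0, 0.5])."""
    i, j = _indices(key)
    raw = gs.incidence_base * gs.incidence_age_slope ** i * gs.incidence_bmi_slope ** j
    return float(min(max(raw, 0.0), 0.5))


def gen_config(key: StratumKey, gs: GeneratorSettings = GeneratorSettings()) -> ModelConfig:
    """A complete runnable config for one stratum.

    Costs/utilities/risks come from the reference preset; incidence from
    :func:`gen_incidence`; screening strategies get sensitivities sampled in
    ``sens_range`` and sorted ascending with interval length, emulating the
    published pattern that longer intervals detect progression more reliably.
    Deterministic given ``gs.seed``.
    """
    i, j = _indices(key)
    rng = np.random.default_rng(np.random.SeedSequence(gs.seed, spawn_key=(i, j)))
    intervals = (1, 3, 6)
    sens = np.sort(rng.uniform(*gs.sens_range, size=len(intervals)))
    spec = rng.uniform(*gs.spec_range, size=len(intervals))
    strategies = tuple(
        TestCharacteristics("annual" if k == 1 else f"{k}-year", k,
                            float(s), float(sp))
        for k, s, sp in zip(intervals, sens, spec))
    cfg = reference_preset(key, annual_incidence=gen_incidence(key, gs), seed=gs.seed)
    return dataclasses.replace(cfg, strategies=strategies)


def gen_bundle(gs: GeneratorSettings = GeneratorSettings(),
               use_reference_strategies: bool = True) -> list[ModelConfig]:
    """Configs for all 12 strata.

    With ``use_reference_strategies`` (default) each stratum keeps the
    published interval-specific test characteristics and only the unpublished
    incidence is synthesized; otherwise strategies are generated too.
    """
    if use_reference_strategies:
        return [reference_preset(k, annual_incidence=gen_incidence(k, gs), seed=gs.seed)
                for k in STRATA]
    return [gen_config(k, gs) for k in STRATA]


def write_fixture_set(out_dir: str | Path, gs: GeneratorSettings = GeneratorSettings(),
                      lt: LifeTable | None = None,
                      use_reference_strategies: bool = True) -> dict[str, Path]:
    """Write a ready-to-run fixture directory: ``configs.yaml`` (12-stratum
    bundle) and ``life_table.csv`` (synthetic Gompertz–Makeham table)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle_path = out_dir / "configs.yaml"
    lt_path = out_dir / "life_table.csv"
    write_bundle(gen_bundle(gs, use_reference_strategies), bundle_path)
    write_life_table(lt if lt is not None else make_gompertz_lifetable(), lt_path)
    return {"configs": bundle_path, "life_table": lt_path}
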