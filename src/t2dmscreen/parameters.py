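"""Model parameterization: domain types, config I/O and consistency checks.

A :class:`ModelConfig` is the complete parameterization of one age x BMI
stratum: the screening strategies under comparison (interval, sensitivity,
specificity), annual costs, health-state utilities, disease risks, economic
settings and, optionally, one sampling distribution per scalar parameter for
probabilistic sensitivity analysis (PSA).

Configs are stored as YAML with a fixed schema; unknown keys are rejected so a
typo never silently becomes a default.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import DistributionError, SchemaError, ValidationError

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")

__all__ = [
    "BMI_CATEGORIES",
    "StratumKey",
    "TestCharacteristics",
    "CostSet",
    "UtilitySet",
    "RiskSet",
    "EconSettings",
    "DistributionSpec",
    "ModelConfig",
    "Finding",
    "load_config",
    "load_bundle",
    "write_config",
    "write_bundle",
    "validate_config",
    "aggregate_utility",
    "distribution_summary",
    "check_psa_consistency",
    "findings_to_frame",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class StratumKey:
    """One cell of the age-band x BMI-category stratification."""

    age_low: int
    age_high: int
    bmi_category: str

    def __post_init__(self) -> None:
        _require(self.age_low < self.age_high,
                 f"age_low ({self.age_low}) must be < age_high ({self.age_high})")
        _require(self.bmi_category in BMI_CATEGORIES,
                 f"bmi_category {self.bmi_category!r} not in {BMI_CATEGORIES}")

    @property
    def label(self) -> str:
        return f"{self.bmi_category}_{self.age_low}-{self.age_high}"


@dataclass(frozen=True)
class TestCharacteristics:
    """One screening strategy: test every ``interval_years`` with the given
    interval-specific sensitivity/specificity."""

    label: str
    interval_years: int
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        _require(self.interval_years >= 1,
                 f"interval_years must be >= 1, got {self.interval_years}")
        _require(0.0 <= self.sensitivity <= 1.0,
                 f"sensitivity must be in [0,1], got {self.sensitivity}")
        _require(0.0 <= self.specificity <= 1.0,
                 f"specificity must be in [0,1], got {self.specificity}")


@dataclass(frozen=True)
class CostSet:
    """Annual costs in USD.

    ``screening_cost`` is charged per administered test; the other three are
    per-year costs of occupying a health state (treated diabetes without /
    with complication, and false-positive follow-up without medication).
    """

    screening_cost: float
    tx_no_comp_annual: float
    tx_comp_annual: float
    fp_annual: float

    def __post_init__(self) -> None:
        for name in ("screening_cost", "tx_no_comp_annual", "tx_comp_annual", "fp_annual"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights (QALY weights), each in [0, 1]."""

    healthy: float
    t2dm_no_comp: float
    t2dm_comp: float

    def __post_init__(self) -> None:
        for name in ("healthy", "t2dm_no_comp", "t2dm_comp"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"utility {name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class RiskSet:
    """Disease dynamics: annual transition probabilities and mortality /
    complication relative risks.

    ``annual_incidence`` (healthy -> undiagnosed diabetes) is stratum-specific
    and has no published value, so it may be left ``None`` and must then be
    supplied before the model can run.  Relative risks act on the hazard scale
    (see :func:`t2dmscreen.life_table.adjusted_mortality`).
    """

    annual_incidence: float | None
    annual_comp_rate: float
    rr_comp_treated: float
    rr_mort_comp: float
    rr_mort_untreated: float
    rr_mort_treated: float = 1.0

    def __post_init__(self) -> None:
        if self.annual_incidence is not None:
            _require(0.0 <= self.annual_incidence <= 1.0,
                     f"annual_incidence must be in [0,1], got {self.annual_incidence}")
        _require(0.0 <= self.annual_comp_rate <= 1.0,
                 f"annual_comp_rate must be in [0,1], got {self.annual_comp_rate}")
        for name in ("rr_comp_treated", "rr_mort_comp", "rr_mort_untreated", "rr_mort_treated"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")


@dataclass(frozen=True)
class EconSettings:
    """Economic and simulation settings.

    ``entry_age=None`` means entry ages are drawn uniformly over the stratum's
    integer age band; an integer fixes every individual's entry age.
    """

    discount_rate: float = 0.02
    wtp: float = 50_000.0
    cohort_size: int = 50_000
    max_age: int = 110
    seed: int = 0
    entry_age: int | None = None

    def __post_init__(self) -> None:
        _require(self.discount_rate >= 0, "discount_rate must be >= 0")
        _require(self.wtp > 0, "wtp must be > 0")
        _require(self.cohort_size >= 1, "cohort_size must be >= 1")
        _require(self.max_age >= 1, "max_age must be >= 1")


_FAMILY_PARAMS = {
    "gamma": ("shape", "scale"),
    "lognormal": ("log_mean", "log_sd"),
    "beta": ("alpha", "beta"),
    "fixed": (),
}


@dataclass(frozen=True)
class DistributionSpec:
    """A PSA sampling distribution plus the base-case point estimate."""

    family: str
    params: Mapping[str, float]
    point_estimate: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_PARAMS:
            raise DistributionError(f"unsupported distribution family {self.family!r}")
        expected = set(_FAMILY_PARAMS[self.family])
        got = set(self.params)
        if got != expected:
            raise ValidationError(
                f"{self.family} distribution needs params {sorted(expected)}, got {sorted(got)}")
        for name, value in self.params.items():
            if name != "log_mean":
                _require(value > 0, f"distribution parameter {name} must be > 0, got {value}")
        _require(math.isfinite(self.point_estimate), "point_estimate must be finite")


#: PSA-samplable scalar parameters: name -> (config section, legal domain).
PSA_PARAMETERS: dict[str, tuple[str, tuple[float, float]]] = {
    "screening_cost": ("costs", (0.0, math.inf)),
    "tx_no_comp_annual": ("costs", (0.0, math.inf)),
    "tx_comp_annual": ("costs", (0.0, math.inf)),
    "fp_annual": ("costs", (0.0, math.inf)),
    "healthy": ("utilities", (0.0, 1.0)),
    "t2dm_no_comp": ("utilities", (0.0, 1.0)),
    "t2dm_comp": ("utilities", (0.0, 1.0)),
    "annual_incidence": ("risks", (0.0, 1.0)),
    "annual_comp_rate": ("risks", (0.0, 1.0)),
    "rr_comp_treated": ("risks", (0.0, math.inf)),
    "rr_mort_comp": ("risks", (0.0, math.inf)),
    "rr_mort_untreated": ("risks", (0.0, math.inf)),
    "rr_mort_treated": ("risks", (0.0, math.inf)),
}


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterization of one stratum's screening model."""

    stratum: StratumKey
    strategies: tuple[TestCharacteristics, ...]
    costs: CostSet
    utilities: UtilitySet
    risks: RiskSet
    settings: EconSettings
    psa: Mapping[str, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategies", tuple(self.strategies))
        object.__setattr__(self, "psa", dict(self.psa))
        for name in self.psa:
            if name not in PSA_PARAMETERS:
                raise ValidationError(f"PSA entry {name!r} names no known scalar parameter")

    def strategy(self, label: str) -> TestCharacteristics:
        for tc in self.strategies:
            if tc.label == label:
                return tc
        raise KeyError(f"no strategy labelled {label!r}")

    def with_values(self, values: Mapping[str, float]) -> "ModelConfig":
        """Return a copy with the named scalar parameters replaced (PSA draws)."""
        sections: dict[str, dict[str, float]] = {}
        for name, value in values.items():
            if name not in PSA_PARAMETERS:
                raise KeyError(f"unknown scalar parameter {name!r}")
            sections.setdefault(PSA_PARAMETERS[name][0], {})[name] = float(value)
        cfg = self
        for section, updates in sections.items():
            cfg = dataclasses.replace(cfg, **{section: dataclasses.replace(getattr(cfg, section), **updates)})
        return cfg


@dataclass(frozen=True)
class Finding:
    """One validation or consistency problem, naming the offending field."""

    field: str
    message: str
    suggested_fix: object | None = None


# ---------------------------------------------------------------------------
# config file I/O

_SECTION_TYPES = {
    "stratum": StratumKey,
    "costs": CostSet,
    "utilities": UtilitySet,
    "risks": RiskSet,
    "settings": EconSettings,
}
_REQUIRED_KEYS = ("stratum", "strategies", "costs", "utilities", "risks", "settings")


def _build_section(cls, raw: object, section: str):
    if not isinstance(raw, dict):
        raise SchemaError(f"section {section!r} must be a mapping")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - fields
    if unknown:
        raise SchemaError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    required = {f.name for f in dataclasses.fields(cls)
                if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING}
    missing = required - set(raw)
    # annual_incidence is declared required but may be explicitly null
    if missing:
        raise SchemaError(f"missing required key(s) {sorted(missing)} in section {section!r}")
    return cls(**raw)


def _config_from_dict(doc: dict) -> ModelConfig:
    if not isinstance(doc, dict):
        raise SchemaError("config document must be a mapping")
    unknown = set(doc) - set(_REQUIRED_KEYS) - {"psa"}
    if unknown:
        raise SchemaError(f"unknown top-level key(s) {sorted(unknown)}")
    missing = set(_REQUIRED_KEYS) - set(doc)
    if missing:
        raise SchemaError(f"missing required section(s) {sorted(missing)}")
    sections = {name: _build_section(cls, doc[name], name) for name, cls in _SECTION_TYPES.items()}
    raw_strats = doc["strategies"]
    if not isinstance(raw_strats, list) or not raw_strats:
        raise SchemaError("'strategies' must be a non-empty list")
    strategies = tuple(_build_section(TestCharacteristics, s, "strategies") for s in raw_strats)
    psa = {}
    for name, raw in (doc.get("psa") or {}).items():
        psa[name] = _build_section(DistributionSpec, raw, f"psa.{name}")
    cfg = ModelConfig(stratum=sections["stratum"], strategies=strategies,
                      costs=sections["costs"], utilities=sections["utilities"],
                      risks=sections["risks"], settings=sections["settings"], psa=psa)
    findings = validate_config(cfg)
    if findings:
        raise ValidationError("; ".join(f"{f.field}: {f.message}" for f in findings))
    return cfg


def _config_to_dict(cfg: ModelConfig) -> dict:
    doc: dict = {}
    doc["stratum"] = dataclasses.asdict(cfg.stratum)
    doc["strategies"] = [dataclasses.asdict(tc) for tc in cfg.strategies]
    for name in ("costs", "utilities", "risks", "settings"):
        doc[name] = dataclasses.asdict(getattr(cfg, name))
    if cfg.psa:
        doc["psa"] = {name: {"family": s.family, "params": dict(s.params),
                             "point_estimate": s.point_estimate}
                      for name, s in cfg.psa.items()}
    return doc


def load_config(path: str | Path) -> ModelConfig:
    """Read and fully validate a single-stratum YAML config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _config_from_dict(doc)


def load_bundle(path: str | Path) -> list[ModelConfig]:
    """Read a multi-stratum bundle (``strata:`` list) or a single config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict) and "strata" in doc:
        unknown = set(doc) - {"strata"}
        if unknown:
            raise SchemaError(f"unknown top-level key(s) {sorted(unknown)} in bundle")
        return [_config_from_dict(d) for d in doc["strata"]]
    return [_config_from_dict(doc)]


def write_config(cfg: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def write_bundle(cfgs: Iterable[ModelConfig], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"strata": [_config_to_dict(c) for c in cfgs]}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# validation

def validate_config(cfg: ModelConfig) -> list[Finding]:
    """Cross-field invariant checks; returns one finding per violation."""
    out: list[Finding] = []
    if len(cfg.strategies) < 2:
        out.append(Finding("strategies", "need at least 2 strategies to compare"))
    labels = [tc.label for tc in cfg.strategies]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        out.append(Finding("strategies", f"duplicate strategy label(s) {dupes}"))
    u = cfg.utilities
    if not (u.healthy >= u.t2dm_no_comp >= u.t2dm_comp):
        out.append(Finding("utilities", "expected ordering healthy >= t2dm_no_comp >= t2dm_comp, "
                           f"got ({u.healthy}, {u.t2dm_no_comp}, {u.t2dm_comp})"))
    c = cfg.costs
    if c.tx_comp_annual < c.tx_no_comp_annual:
        out.append(Finding("costs", "expected tx_comp_annual >= tx_no_comp_annual"))
    r = cfg.risks
    if not (r.rr_mort_comp >= r.rr_mort_untreated >= r.rr_mort_treated):
        out.append(Finding("risks", "expected ordering rr_mort_comp >= rr_mort_untreated >= rr_mort_treated"))
    if r.annual_incidence is None:
        out.append(Finding("risks.annual_incidence",
                           "no published value exists; a stratum-specific value must be supplied"))
    if cfg.settings.max_age <= cfg.stratum.age_high:
        out.append(Finding("settings.max_age",
                           f"max_age ({cfg.settings.max_age}) must exceed the stratum's "
                           f"age_high ({cfg.stratum.age_high})"))
    return out


# ---------------------------------------------------------------------------
# scalar helpers

def aggregate_utility(utilities: Sequence[float], weights: Sequence[float]) -> float:
    """Proportion-weighted mean of utility values.

    Used to collapse complication-specific utilities into the single
    any-complication utility the model carries (the reference analysis does
    the same with published complication proportions).
    """
    if len(utilities) != len(weights):
        raise ValidationError("utilities and weights must have equal length")
    if any(w < 0 for w in weights):
        raise ValidationError("weights must be >= 0")
    total = math.fsum(weights)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"weights must sum to 1 (got {total!r})")
    return math.fsum(w * u for w, u in zip(weights, utilities))


def distribution_summary(spec: DistributionSpec) -> dict[str, float]:
    """Closed-form mean and median of a :class:`DistributionSpec`.

    gamma: mean = shape*scale; beta: mean = alpha/(alpha+beta);
    lognormal: median = exp(log_mean), mean = exp(log_mean + log_sd^2/2);
    fixed: point estimate for both.  Medians without a convenient closed form
    (gamma, beta) are reported as NaN.
    """
    p = spec.params
    if spec.family == "gamma":
        return {"mean": p["shape"] * p["scale"], "median": math.nan}
    if spec.family == "beta":
        return {"mean": p["alpha"] / (p["alpha"] + p["beta"]), "median": math.nan}
    if spec.family == "lognormal":
        return {"mean": math.exp(p["log_mean"] + p["log_sd"] ** 2 / 2),
                "median": math.exp(p["log_mean"])}
    if spec.family == "fixed":
        return {"mean": spec.point_estimate, "median": spec.point_estimate}
    raise DistributionError(f"unsupported distribution family {spec.family!r}")


def check_psa_consistency(cfg: ModelConfig, rel_tol: float = 0.05) -> list[Finding]:
    """Compare each PSA distribution's central value with its point estimate.

    The central value is the mean, except for lognormal where the median is
    the natural centre (relative risks are reported as medians).  When the
    relative deviation exceeds ``rel_tol`` a finding is emitted; for gamma
    specs the finding carries a corrected spec with the scale rescaled so that
    shape*scale equals the point estimate (shape, hence the coefficient of
    variation's order of magnitude, is kept).
    """
    out: list[Finding] = []
    for name, spec in cfg.psa.items():
        if spec.family == "fixed":
            continue
        summ = distribution_summary(spec)
        centre = summ["median"] if spec.family == "lognormal" else summ["mean"]
        point = spec.point_estimate
        denom = abs(point) if point != 0 else 1.0
        if abs(centre - point) / denom <= rel_tol:
            continue
        fix = None
        if spec.family == "gamma":
            fix = DistributionSpec("gamma",
                                   {"shape": spec.params["shape"],
                                    "scale": point / spec.params["shape"]},
                                   point)
        out.append(Finding(
            name,
            f"{spec.family} centre {centre:.6g} deviates from point estimate {point:.6g} "
            f"by {abs(centre - point) / denom:.1%} (> {rel_tol:.0%})",
            fix))
    return out


def findings_to_frame(findings: Sequence[Finding]):
    """Findings as a pandas DataFrame with columns (field, finding, suggested_fix)."""
    import pandas as pd

    return pd.DataFrame(
        [{"field": f.field, "finding": f.message,
          "suggested_fix": "" if f.suggested_fix is None else str(f.suggested_fix)}
         for f in findings],
        columns=["field", "finding", "suggested_fix"])
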