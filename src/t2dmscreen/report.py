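"""Tabular output writers and the run manifest.

Formatting mirrors the published tables: costs and QALYs to 2 decimals in
the presentation CSV, with a companion raw CSV at full precision; the
recommendation matrix has BMI categories as rows and age bands as columns.
"""

from __future__ import annotations

import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .cea import CEATable
from .microsim import StrategyResult
from .parameters import StratumKey

__all__ = ["cea_table_frame", "write_cea_tables", "write_recommendation_matrix",
           "write_strategy_results", "write_manifest"]

_STATUS_DISPLAY = {"dominated": "Dominated", "extended_dominated": "Dominated",
                   "dominant": "Dominant", "frontier": ""}


def cea_table_frame(tables: list[CEATable], rounded: bool = True) -> pd.DataFrame:
    """Stacked incremental-analysis rows for one or more strata."""
    rows = []
    for tab in tables:
        name = tab.stratum.label if tab.stratum is not None else ""
        for r in tab.rows:
            rec = {"stratum": name, "strategy": r.label, "qaly": r.qaly,
                   "incr_qaly": r.delta_qaly, "cost": r.cost,
                   "incr_cost": r.delta_cost, "icer": r.icer,
                   "status": _STATUS_DISPLAY[r.status] if rounded else r.status,
                   "comparator": r.comparator_label or ""}
            if rounded:
                for col in ("qaly", "incr_qaly", "cost", "incr_cost", "icer"):
                    if rec[col] is not None:
                        rec[col] = round(rec[col], 2)
            rows.append(rec)
    return pd.DataFrame(rows)


def write_cea_tables(tables: list[CEATable], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    cea_table_frame(tables, rounded=True).to_csv(out_dir / "cea_table.csv", index=False)
    cea_table_frame(tables, rounded=False).to_csv(out_dir / "cea_table_raw.csv", index=False)


def write_recommendation_matrix(tables: list[CEATable], out_dir: str | Path) -> Path:
    """Recommended interval per stratum, BMI categories x age bands."""
    from .reference import AGE_BANDS, BMI_ORDER

    cols = [f"{lo}-{hi}" for lo, hi in AGE_BANDS]
    mat = pd.DataFrame(index=list(BMI_ORDER), columns=cols, dtype=object)
    mat.index.name = "bmi_category"
    for tab in tables:
        s = tab.stratum
        if s is None:
            continue
        mat.loc[s.bmi_category, f"{s.age_low}-{s.age_high}"] = tab.recommendation
    path = Path(out_dir) / "recommendations.csv"
    mat.to_csv(path)
    return path


def write_strategy_results(results: list[tuple[StratumKey, StrategyResult]],
                           out_dir: str | Path) -> Path:
    rows = [{"stratum": key.label, "strategy": r.strategy_label, "n": r.n,
             "seed": r.seed, "mean_cost": r.mean_cost, "se_cost": r.se_cost,
             "mean_qaly": r.mean_qaly, "se_qaly": r.se_qaly}
            for key, r in results]
    path = Path(out_dir) / "strategy_results.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_manifest(out_dir: str | Path, command: str, seed: int,
                   inputs: dict[str, str], **extra) -> Path:
    """Record everything needed to re-run an output set bit-identically."""
    from . import __version__

    manifest = {"command": command, "argv": sys.argv, "seed": seed,
                "inputs": inputs, "version": __version__,
                "timestamp": datetime.now(timezone.utc).isoformat(), **extra}
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
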