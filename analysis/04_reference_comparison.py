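"""Incremental analysis of the published outcome table.

Feeds the published per-strategy (QALY, cost) means through the package's
dominance/ICER/recommendation logic and compares against the published
dominance labels and the 12-entry recommended-interval matrix.  Two strata
(normal 30-44 and overweight 45-59) are expected to disagree: their printed
rounded outcomes are inconsistent with the published unrounded ICERs.
Writes results/reference/.
"""

from pathlib import Path

from t2dmscreen.cea import build_cea_table
from t2dmscreen.reference import (REFERENCE_RECOMMENDATIONS, STRATA,
                                  reference_outcomes)
from t2dmscreen.report import write_cea_tables, write_recommendation_matrix

OUT = Path(__file__).resolve().parent.parent / "results" / "reference"
WTP = 50_000.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = [build_cea_table(reference_outcomes(k), WTP, stratum=k) for k in STRATA]
    write_cea_tables(tables, OUT)
    write_recommendation_matrix(tables, OUT)
    matches = 0
    for k, tab in zip(STRATA, tables):
        expected = REFERENCE_RECOMMENDATIONS[(k.bmi_category, k.age_low)]
        flag = "ok" if tab.recommendation == expected else "MISMATCH"
        matches += tab.recommendation == expected
        print(f"{k.label:24s} computed {tab.recommendation:8s} "
              f"published {expected:8s} {flag}")
    print(f"{matches}/12 recommendations agree with the published matrix")


if __name__ == "__main__":
    main()
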