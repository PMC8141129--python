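"""Build the model inputs: the 12 stratum configs and the synthetic life table.

The published parameterization covers screening test characteristics, costs,
utilities and risks, but not background mortality or stratum incidence; those
two are synthesized (Gompertz-Makeham mortality, multiplicative incidence).
Writes results/inputs/configs.yaml and results/inputs/life_table.csv.
"""

from pathlib import Path

from t2dmscreen.life_table import life_expectancy, make_gompertz_lifetable
from t2dmscreen.parameters import load_bundle
from t2dmscreen.synthetic import GeneratorSettings, gen_incidence, write_fixture_set
from t2dmscreen.reference import STRATA

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = 1


def main() -> None:
    gs = GeneratorSettings(seed=SEED)
    paths = write_fixture_set(OUT, gs)
    lt = make_gompertz_lifetable()
    print(f"wrote {paths['configs']} and {paths['life_table']}")
    print(f"synthetic life table: life expectancy at 30 = {life_expectancy(lt, 30):.1f} y, "
          f"at 60 = {life_expectancy(lt, 60):.1f} y")
    print("synthetic annual incidence by stratum:")
    for k in STRATA:
        print(f"  {k.label:24s} {gen_incidence(k, gs):.4f}")
    n = len(load_bundle(paths["configs"]))
    print(f"bundle round-trips: {n} strata load cleanly")


if __name__ == "__main__":
    main()
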