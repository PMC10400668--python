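#!/usr/bin/env python
"""Generate the default synthetic warming × CO2 experiment.

Writes the three input tables the downstream analyses consume —
`aci_curves.csv` (96+ A–Ci temperature-response curves across 10
plots, 2 species, 2 campaign months), `climate.csv` (half-hourly
per-plot air temperature) and `truth.csv` (the per-tree thermal
parameters the generator embedded, for recovery scoring) — under
results/synthetic/.
"""

from pathlib import Path

from thermacclim.synthetic import SyntheticConfig, generate_experiment

OUT = Path("results/synthetic")
SEED = 1


def main() -> None:
    config = SyntheticConfig()
    exp = generate_experiment(config, SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    for name in ("aci_curves", "climate", "truth"):
        exp[name].to_csv(OUT / f"{name}.csv", index=False)
    curves = exp["aci_curves"]
    n_curves = len(curves) // 11
    print(f"seed {SEED}: generated {n_curves} A-Ci curves "
          f"({curves.plot_id.nunique()} plots, "
          f"{curves.species.nunique()} species, "
          f"{curves.month.nunique()} months, 5 leaf temperatures), "
          f"{len(exp['truth'])} tree-month truths -> {OUT}/")


if __name__ == "__main__":
    main()
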