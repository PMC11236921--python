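"""Generate the synthetic study city: a 12 x 8 tract lattice (96 tracts)
with spatially clustered racial composition, correlated SES covariates and
ZIP-BYM store counts, written as plain-text inputs for the later stages.

Run:  python analysis/01_simulate_city.py [--seed 1] [--out results/city]
"""

import argparse
from pathlib import Path

from fooddesert.simulate import SimulationConfig, simulate_bundle, write_bundle


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/city")
    args = ap.parse_args()

    bundle = simulate_bundle(SimulationConfig(seed=args.seed))
    out = write_bundle(bundle, Path(args.out))
    y = bundle.area_table.y
    print(f"wrote {bundle.graph.n}-tract bundle to {out}")
    print(f"  store counts: mean {y.mean():.2f}, zeros {(y == 0).mean():.0%}")
    print(f"  graph: {bundle.graph.summary()}")
    print(f"  truth: pi0={bundle.config.pi0}, tau_u={bundle.config.tau_u}, "
          f"tau_v={bundle.config.tau_v}")


if __name__ == "__main__":
    main()
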