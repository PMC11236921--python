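"""Model comparison (DIC / pD, the Table-3 analogue) and exceedance-probability
hotspot summary for the fitted models.

Run:  python analysis/04_compare_and_hotspots.py [--fits results/fits]
"""

import argparse
import json
from pathlib import Path

import pandas as pd


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fits", default="results/fits")
    args = ap.parse_args()

    fits = Path(args.fits)
    comp = pd.read_csv(fits / "comparison.csv").set_index("model")
    print("DIC model comparison (lower is better; >= 3-point gap = substantial):")
    print(comp.round(2).to_string())
    best = comp.index[comp["preferred"]].tolist()
    if best:
        print(f"\npreferred model: {best[0]} "
              f"(evidence: {comp.loc[best[0], 'evidence'] or 'weak'})")

    print("\nexceedance classes per model (threshold exp(u+v) > 1; "
          "p<0.2 coldspot, p>=0.8 hotspot):")
    for m in (1, 2, 3, 4):
        path = fits / f"model{m}_exceedance.csv"
        if not path.exists():
            continue
        exc = pd.read_csv(path)
        counts = exc["class"].value_counts().to_dict()
        print(f"  model {m}: " + ", ".join(
            f"{counts.get(k, 0)} {k}" for k in ("coldspot", "neither", "hotspot")))

    with open(fits / "manifest.json") as fh:
        man = json.load(fh)
    print(f"\nrun seed {man['config']['seed']}, wall time {man['wall_time_s']}s")


if __name__ == "__main__":
    main()
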