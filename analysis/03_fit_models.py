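"""Fit the four nested ZIP-BYM models to the synthetic city and write the
rate-ratio summary tables (the Table-2 analogue), draws archives, and
exceedance classifications.

This is a thin driver over fooddesert.pipeline.run_pipeline.

Run:  python analysis/03_fit_models.py [--city results/city] [--seed 1]
      [--n-iter 20000] [--n-burn 10000] [--chains 4]
"""

import argparse
from pathlib import Path

import pandas as pd

from fooddesert.pipeline import RunConfig, run_pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--city", default="results/city")
    ap.add_argument("--out", default="results/fits")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-iter", type=int, default=20_000)
    ap.add_argument("--n-burn", type=int, default=10_000)
    ap.add_argument("--chains", type=int, default=4)
    args = ap.parse_args()

    city = Path(args.city)
    cfg = RunConfig(
        area_table=str(city / "area_table.csv"),
        adjacency=str(city / "adjacency.tsv"),
        output_dir=args.out,
        seed=args.seed,
        n_iter=args.n_iter,
        n_burn=args.n_burn,
        n_chains=args.chains,
    )
    out = run_pipeline(cfg)
    for m in (1, 2, 3, 4):
        summ = pd.read_csv(out / f"model{m}_summary.csv")
        print(f"\nmodel {m} rate ratios (RR, 95% CI; * = CI excludes 1):")
        for _, row in summ.iterrows():
            star = "*" if row["significant"] else " "
            print(f"  {row['coefficient']:>22} {row['rr_mean']:.2f}{star} "
                  f"({row['ci_low']:.2f}-{row['ci_high']:.2f})")
    print(f"\nartifacts in {out}")


if __name__ == "__main__":
    main()
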