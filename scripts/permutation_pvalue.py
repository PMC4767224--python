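#!/usr/bin/env python
"""Utility: frequentist permutation p-value for LOO classification accuracy.

Such a cross-validation check is redundant when the predictive densities
come from independent training folds, but it is occasionally requested by
reviewers.  Given a fold table produced by `pebkit loo` (CSV with `truth`
and `predicted` columns), this script permutes the truth labels and reports
the probability of matching or exceeding the observed accuracy by chance.

Usage:
    python scripts/permutation_pvalue.py loo.csv --n-permutations 10000 --seed 1
"""

import argparse

import numpy as np
import pandas as pd


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("table", help="fold table CSV from `pebkit loo`")
    parser.add_argument("--n-permutations", type=int, default=10_000)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    df = pd.read_csv(args.table)
    truth = df["truth"].to_numpy()
    pred = df["predicted"].to_numpy()
    observed = float((truth == pred).mean())
    rng = np.random.default_rng(args.seed)
    null = np.array(
        [
            (rng.permutation(truth) == pred).mean()
            for _ in range(args.n_permutations)
        ]
    )
    p = float((null >= observed).mean() + 1.0 / args.n_permutations)
    print(f"observed accuracy: {observed:.3f}")
    print(f"permutation p-value (n={args.n_permutations}): {min(p, 1.0):.4g}")


if __name__ == "__main__":
    main()
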