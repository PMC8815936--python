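#!/usr/bin/env python
"""Tight linkage: selection destroys diversity-based Ne, not LD-based Ne.

Q = 5 rescale of the extreme scenario where the whole genome spans about
1 cM.  Under background selection, linked purifying selection collapses
nucleotide diversity (so pi/(4 mu) badly underestimates the census
size), while the LD-based estimate barely moves — the separation the
whole study turns on.

Writes results/tight_linkage_ne.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ldne.scenarios import pooled_tight_linkage_ne

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=10)
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)

    rows = []
    for model in ("neutral", "bs"):
        seeds = rng.integers(0, 2 ** 31 - 1, size=args.replicates)
        rows.append(pooled_tight_linkage_ne(model, seeds))
        r = rows[-1]
        print(f"{model:8s}: Ne_LD = {r['ne_ld']:6.0f}  Ne_pi = {r['ne_pi']:6.0f} "
              f"(true scaled N = 200, {r['n_pairs']} pooled pairs)")
    neutral, bs = rows
    print(f"BS/neutral ratios: Ne_pi = {bs['ne_pi'] / neutral['ne_pi']:.2f} "
          f"(diversity collapses), Ne_LD = {bs['ne_ld'] / neutral['ne_ld']:.2f} "
          "(the LD estimate moves far less, though not nothing at this extreme)")

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "tight_linkage_ne.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
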