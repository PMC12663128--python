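#!/usr/bin/env python
"""Fit the distribution-free Taylor-polynomial model and export centiles.

Reads a person-level CSV, derives each person's location from the
within-cohort inverse normal-rank transformation, fits the polynomial
raw-score surface by exact best-subset regression, reports the selected
terms and coherence status, and writes a norm table.
"""

import argparse
from pathlib import Path

import numpy as np

import normbench as nb


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path, default=Path("results/data/vo2max_like.csv"))
    ap.add_argument("--k", type=int, default=5)
    ap.add_argument("--t", type=int, default=3)
    ap.add_argument("--max-terms", type=int, default=8)
    ap.add_argument("--out", type=Path, default=Path("results/cnorm_norm_table.csv"))
    args = ap.parse_args()

    data = nb.read_norm_data(args.input)
    cfg = nb.CNormConfig(k=args.k, t_power=args.t, max_terms=args.max_terms)
    model = nb.fit_cnorm(data, cfg)
    d = model.diagnostics
    print(f"candidate terms: {(args.k + 1) * (args.t + 1)}; selection: {d['selection']}")
    print(f"selected size {d['selected_size']}, in-sample R^2 = {d['r2']:.5f}")
    print("terms (theta power, age power) -> coefficient:")
    for (i, j), c in zip(model.terms, model.coefficients):
        print(f"  ({i}, {j}) -> {c:+.4f}")
    print(f"coherence (raw score strictly increasing in theta on [20, 80]): {model.coherence_passed}")

    if model.coherence_passed:
        lo, hi = model.age_range
        ages = np.arange(np.ceil(lo * 2) / 2, hi, 0.5)
        table = nb.norm_table_cnorm(model, ages, [0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97])
        args.out.parent.mkdir(parents=True, exist_ok=True)
        nb.write_norm_table(table, args.out)
        print(f"wrote {len(ages)}-age x 7-centile norm table to {args.out}")


if __name__ == "__main__":
    main()
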