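#!/usr/bin/env python
"""Fit the parametric LMS model to a simulated sample and export centiles.

Reads a person-level CSV (defaults to the VO2max-like sample from
01_simulate.py), fits smooth L(t), M(t), S(t) curves by penalized
likelihood, reports fit diagnostics and the calibration of the implied
z-scores, and writes a norm table of centile cut-offs.
"""

import argparse
from pathlib import Path

import numpy as np

import normbench as nb


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path, default=Path("results/data/vo2max_like.csv"))
    ap.add_argument("--edf-l", type=float, default=2.0)
    ap.add_argument("--edf-m", type=float, default=4.0)
    ap.add_argument("--edf-s", type=float, default=3.0)
    ap.add_argument("--out", type=Path, default=Path("results/lms_norm_table.csv"))
    args = ap.parse_args()

    data = nb.read_norm_data(args.input)
    report = nb.validate_for_method(data, "LMS")
    for v in report:
        print(f"[{v.severity}] {v.message}")
    cfg = nb.LMSFitConfig(edf_L=args.edf_l, edf_M=args.edf_m, edf_S=args.edf_s)
    model = nb.fit_lms(data, cfg)
    info = model.fit_info
    print(
        f"fit: {info.iterations} iterations, converged={info.converged}, "
        f"penalized log-likelihood {info.penalized_loglik:.2f}"
    )
    z = nb.z_score(model, data.scores, data.ages)
    print(f"z-score calibration: mean {np.mean(z):+.4f} (target 0), SD {np.std(z):.4f} (target 1)")

    lo, hi = model.age_range
    ages = np.arange(np.ceil(lo * 2) / 2, hi, 0.5)
    table = nb.norm_table_lms(model, ages, [0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97])
    args.out.parent.mkdir(parents=True, exist_ok=True)
    nb.write_norm_table(table, args.out)
    print(f"wrote {len(ages)}-age x 7-centile norm table to {args.out}")


if __name__ == "__main__":
    main()
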