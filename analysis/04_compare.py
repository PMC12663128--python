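#!/usr/bin/env python
"""Cross-validated comparison of the two norming methods.

Repeated stratified sampling: for each training size (cases per one-year
cohort) and repetition, both methods are fitted on the training draw and
predict T scores for the held-out records, judged against the benchmark
T_actual from the complete sample's inverse normal-rank transformation.
Writes per-run metrics and a mean ± SE summary per method x size x region,
and optionally a figure of the RMSE/Bias trends.
"""

import argparse
from pathlib import Path

import normbench as nb


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path, default=Path("results/data/vo2max_like.csv"))
    ap.add_argument("--sizes", type=str, default="50,100,150,200")
    ap.add_argument("--reps", type=int, default=20)
    ap.add_argument("--base-seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results/comparison_runs.csv"))
    ap.add_argument("--summary-out", type=Path, default=Path("results/comparison_summary.csv"))
    ap.add_argument("--plot", type=Path, default=None)
    args = ap.parse_args()

    data = nb.read_norm_data(args.input)
    sizes = tuple(int(s) for s in args.sizes.split(","))
    spec = nb.SplitSpec(sizes=sizes, repetitions=args.reps, base_seed=args.base_seed)
    print(f"running {args.reps} repetitions x {len(sizes)} sizes x 2 methods ...")
    results = nb.run_comparison(data, spec)
    frame = nb.results_to_frame(results)
    summary = nb.summarize(results)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, index=False, float_format="%.6g")
    summary.to_csv(args.summary_out, index=False, float_format="%.6g")
    print(f"wrote {len(frame)} run rows to {args.out}")

    full = summary[summary.region == "full"].set_index(["method", "n_per_cohort"])
    for method in ("lms", "cnorm"):
        trend = ", ".join(
            f"n={s}: {full.loc[(method, s), 'rmse_mean']:.2f}" for s in sizes
        )
        print(f"{method} full-range mean RMSE (T-units) by training size: {trend}")
    tails = summary[summary.region != "full"].set_index(["method", "n_per_cohort", "region"])
    for region in ("lower", "upper"):
        a = tails.loc[("cnorm", sizes[0], region), "rmse_mean"]
        b = tails.loc[("lms", sizes[0], region), "rmse_mean"]
        print(f"{region}-tail mean RMSE at n={sizes[0]}: cnorm {a:.2f} vs lms {b:.2f}")

    if args.plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        styles = {"full": "-", "lower": ":", "upper": "--"}
        colors = {"lms": "tab:blue", "cnorm": "tab:orange"}
        for metric, ax in zip(("rmse", "bias"), axes):
            for method in ("lms", "cnorm"):
                for region, ls in styles.items():
                    sub = summary[(summary.method == method) & (summary.region == region)]
                    ax.errorbar(
                        sub.n_per_cohort, sub[f"{metric}_mean"], yerr=sub[f"{metric}_se"],
                        ls=ls, color=colors[method], label=f"{method} {region}",
                    )
            ax.set_xlabel("training cases per cohort")
            ax.set_ylabel(f"{metric.upper()} (T-units)")
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        args.plot.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(args.plot, dpi=150)
        print(f"wrote figure to {args.plot}")


if __name__ == "__main__":
    main()
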