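"""Screen the normalized panel for differentially expressed miRNAs: per-probe
Student t-test, Benjamini-Hochberg adjustment at 0.05, exp-scale fold
changes, per-probe AUC; rank by absolute log fold change.

Reads results/expression_normalized.tsv, writes results/diffexp.tsv, and
scores the calls against the generator's planted truth.
"""

import argparse

import pandas as pd

from mirblood.diffexp import rank_by_fold_change, run_diffexp, shapiro_median
from mirblood.io import read_expression_tsv, read_labels_tsv, write_diffexp_tsv
from mirblood.preprocess import ExpressionMatrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--expression", default="results/expression_normalized.tsv")
    ap.add_argument("--labels", default="results/cohort/labels.tsv")
    ap.add_argument("--truth", default="results/cohort/truth.tsv")
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out", default="results/diffexp.tsv")
    args = ap.parse_args()

    expr = ExpressionMatrix(values=read_expression_tsv(args.expression),
                            labels=read_labels_tsv(args.labels))
    sw, _ = shapiro_median(expr)
    table = rank_by_fold_change(run_diffexp(expr, alpha=args.alpha))
    write_diffexp_tsv(table, args.out)

    sig = table[table["significant"]]
    up = (sig["direction"] == "up").sum()
    print(f"Shapiro-Wilk median p across probes: {sw:.3g}")
    print(f"{len(sig)} significant probes at adjusted p < {args.alpha} "
          f"({up} up / {len(sig) - up} down); table: {args.out}")
    print("top rows (medians, fold change, adjusted p, AUC):")
    cols = ["median_control", "median_case", "fold_change", "p_adjusted", "auc"]
    print(table[cols].head(8).round(3).to_string())

    try:
        truth = pd.read_csv(args.truth, sep="\t", index_col=0)
    except FileNotFoundError:
        return
    planted = truth["is_differential"].reindex(table.index).fillna(False)
    tp = (table["significant"] & planted).sum()
    fp = int(table["significant"].sum()) - tp
    print(f"vs planted truth: {tp}/{planted.sum()} planted probes recovered, "
          f"{fp} false discoveries (FDP {fp / max(tp + fp, 1):.3f})")


if __name__ == "__main__":
    main()
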