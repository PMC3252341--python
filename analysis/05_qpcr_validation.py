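"""RT-qPCR validation on an independent matched-pair cohort: simulate 24
age-matched pairs measured in duplicate wells for two target miRNAs plus the
miR-16 endogenous reference, then quantify each target by the comparative-Ct
method (2^-ddCt), t-test on delta-Ct, and delta-Ct ROC/AUC.

One target is planted up-regulated, one down-regulated, mirroring a
discovery screen that nominated one probe of each direction.
"""

import argparse

import pandas as pd

from mirblood.io import write_qpcr_table
from mirblood.qpcr import qpcr_compare
from mirblood.synthetic import generate_qpcr_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--pairs", type=int, default=24)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    planted = {"miR-val-up": 1.0, "miR-val-down": -1.2}  # log2 fold in cases
    table = generate_qpcr_cohort(n_pairs=args.pairs, true_log2_fold=planted,
                                 ct_noise_sd=0.25, seed=args.seed)
    write_qpcr_table(table, f"{args.outdir}/qpcr_ct.tsv")

    rows = []
    for target, true_l2f in planted.items():
        r = qpcr_compare(table, target)
        rows.append({
            "mirna_id": target,
            "fold_magnitude": round(r.fold.magnitude, 2),
            "direction": r.fold.direction,
            "p_value": round(r.p_value, 4),
            "auc": round(r.auc, 2),
            "planted_fold": round(2.0 ** abs(true_l2f), 2),
        })
        r.delta_ct_table.to_csv(f"{args.outdir}/qpcr_delta_ct_{target}.tsv",
                                sep="\t", float_format="%.6g")
    out = pd.DataFrame(rows)
    out.to_csv(f"{args.outdir}/qpcr_results.tsv", sep="\t", index=False)
    print(f"validation cohort: {args.pairs} matched pairs, duplicate wells, "
          "miR-16 reference")
    print(out.to_string(index=False))
    print("(fold_magnitude is the 2^-ddCt group fold, reported >= 1 with a direction;"
          " AUC uses -dCt so higher expression scores higher)")


if __name__ == "__main__":
    main()
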