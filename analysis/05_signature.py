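#!/usr/bin/env python
"""Diagnostic signature: LASSO selection, random forest, ROC, CV.

Takes the disease-specific genes, splits samples 80/20 stratified by
group, selects features by 10-fold cross-validated L1 logistic
regression on the training set, fits a 1000-tree bagged regression
forest on the retained genes, and reports train/validation AUC plus a
5-fold cross-validation of the whole selection + fit pipeline.
Outputs land under results/signature.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from cerna_forge import io_prep, signature as sig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--trees", type=int, default=1000)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    prep = args.results / "prep"
    mrna = io_prep.read_expression(prep / "mrna_corrected.tsv")
    samples = io_prep.read_sample_table(prep / "samples.tsv")
    specific = pd.read_csv(
        args.results / "wgcna" / "disease_specific_genes.tsv", sep="\t"
    )["gene"].tolist()
    xs = mrna.loc[specific]

    train_t, valid_t = sig.split_train_validation(samples, 0.8, seed=args.seed)
    tr = train_t["sample_id"].tolist()
    va = valid_t["sample_id"].tolist()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        selected = sig.lasso_select(xs[tr], train_t, n_folds=10, seed=args.seed)
    feats = [g for g, _ in selected] or specific
    model = sig.rf_fit_and_importance(xs.loc[feats, tr], train_t,
                                      n_trees=args.trees, seed=args.seed)
    roc_tr = sig.evaluate_roc(model, xs.loc[feats, tr], train_t)
    roc_va = sig.evaluate_roc(model, xs.loc[feats, va], valid_t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv_auc, cv_folds = sig.cross_validate(xs, samples, n_folds=5, seed=args.seed)

    out = args.results / "signature"
    out.mkdir(parents=True, exist_ok=True)
    for roc, name in ((roc_tr, "roc_train.tsv"), (roc_va, "roc_valid.tsv")):
        pd.DataFrame({
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }).to_csv(out / name, sep="\t", index=False)
    with open(out / "signature.json", "wt", encoding="utf-8") as fh:
        json.dump({
            "features": model.features,
            "lasso_coefficients": dict(selected),
            "n_trees": model.n_trees,
            "seed": args.seed,
            "importance": model.importance.to_dict(),
            "train_auc": roc_tr.auc,
            "valid_auc": roc_va.auc,
            "cv_mean_auc": cv_auc,
            "cv_fold_aucs": cv_folds,
        }, fh, indent=1)

    print(f"{len(specific)} candidates -> LASSO kept {len(feats)}: {feats}")
    print(model.importance.sort_values("%IncMSE", ascending=False).round(2).to_string())
    print(f"train AUC = {roc_tr.auc:.3f}; validation AUC = {roc_va.auc:.3f}; "
          f"5-fold CV mean AUC = {cv_auc:.3f}")


if __name__ == "__main__":
    main()
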