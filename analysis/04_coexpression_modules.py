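#!/usr/bin/env python
"""Weighted co-expression modules and the disease-specific gene funnel.

Keeps the top 25% most variable genes, selects a soft power targeting
scale-free fit R^2 >= 0.85 (falling back to the sample-size default if
the factor structure is not scale-free), builds the TOM, detects
modules (minimum size 50, eigengene merge at 0.15), correlates module
eigengenes with the case trait, and intersects the DE genes with the
two most trait-associated modules.  Outputs land under results/wgcna.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from cerna_forge import coexpr, io_prep


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    prep = args.results / "prep"
    mrna = io_prep.read_expression(prep / "mrna_corrected.tsv")
    samples = io_prep.read_sample_table(prep / "samples.tsv")
    de_mrna = pd.read_csv(args.results / "de" / "de_mrna.tsv", sep="\t",
                          index_col="feature_id")

    xw = coexpr.select_top_variance(mrna, 0.25)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = coexpr.pick_soft_threshold(xw, range(1, 13), 0.85,
                                            fallback="sample-size")
    tom = coexpr.compute_tom(xw, report.selected)
    assign = coexpr.detect_modules(tom, xw, min_module_size=50, merge_cut_height=0.15)
    mt = coexpr.module_trait(assign, samples)
    assign = coexpr.gene_stats(assign, xw, samples)

    ranked = mt.reindex(mt["r"].abs().sort_values(ascending=False).index)
    selected = [m for m in ranked.index][:2]
    specific = coexpr.disease_specific_genes(de_mrna, assign, selected)

    out = args.results / "wgcna"
    out.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
    mt.to_csv(out / "module_trait.tsv", sep="\t")
    assign.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
    own_mm = [
        assign.mm.loc[g, assign.modules[g]] if assign.modules[g] != coexpr.GREY
        else np.nan
        for g in assign.modules.index
    ]
    pd.DataFrame({"module": assign.modules, "MM": own_mm, "GS": assign.gs}) \
        .rename_axis("gene").to_csv(out / "modules.tsv", sep="\t")
    pd.Series(specific, name="gene").to_csv(out / "disease_specific_genes.tsv",
                                            sep="\t", index=False)

    sizes = assign.modules[assign.modules != coexpr.GREY].value_counts()
    print(f"soft power beta = {report.selected} (target met: {report.target_met})")
    print(f"modules: {sizes.to_dict()}")
    print("module-trait correlations:")
    print(mt[["r", "p"]].round(4).to_string())
    print(f"selected modules {selected} ∩ DE genes -> "
          f"{len(specific)} disease-specific genes")


if __name__ == "__main__":
    main()
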