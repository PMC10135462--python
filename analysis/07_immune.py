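#!/usr/bin/env python
"""ssGSEA immune scoring, hub-gene correlation and group comparison.

Scores each immune signature set per sample with the rank-weighted
running-sum statistic (alpha = 0.25, matrix-wide min-max normalised),
correlates the pruned hub mRNAs with the cell-type scores (Spearman)
and compares case vs control scores per cell type (Mann-Whitney U).
Outputs land under results/immune.
"""

import argparse
from pathlib import Path

import pandas as pd

from cerna_forge import immune, io_prep


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    prep = args.results / "prep"
    mrna = io_prep.read_expression(prep / "mrna_corrected.tsv")
    samples = io_prep.read_sample_table(prep / "samples.tsv")
    sets = immune.read_gmt(args.results / "bundle" / "immune_sets.gmt")
    triplets = pd.read_csv(args.results / "cerna" / "triplets.tsv", sep="\t")
    hub_mrnas = sorted(set(triplets["mrna"]))

    scores = immune.ssgsea_scores(mrna, sets, alpha=0.25)
    comp = immune.compare_groups(scores, samples)

    out = args.results / "immune"
    out.mkdir(parents=True, exist_ok=True)
    scores.rename_axis("gene_set").to_csv(out / "ssgsea_scores.tsv", sep="\t")
    comp.to_csv(out / "group_comparison.tsv", sep="\t", index=False)
    print("case-vs-control score comparison:")
    print(comp.round(4).to_string(index=False))
    if hub_mrnas:
        corr = immune.correlate_hub_scores(mrna, hub_mrnas, scores)
        corr.to_csv(out / "hub_immune_correlation.tsv", sep="\t", index=False)
        top = corr.sort_values("rho", ascending=False).head(5)
        print("strongest hub-gene / cell-type correlations:")
        print(top.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
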