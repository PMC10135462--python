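#!/usr/bin/env python
"""Moderated-t differential expression for both molecular layers.

Applies the empirical-Bayes moderated t test case-vs-control to the
batch-corrected mRNA matrix (calling DE at adj p < 0.05 and |log2FC| >
0.58) and to the miRNA matrix (adj p < 0.05 and |log2FC| > 2), and
writes the DE tables under results/de.
"""

import argparse
from pathlib import Path

from cerna_forge import diffexpr, io_prep


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    prep = args.results / "prep"
    mrna = io_prep.read_expression(prep / "mrna_corrected.tsv")
    mirna = io_prep.read_expression(prep / "mirna.tsv")
    samples = io_prep.read_sample_table(prep / "samples.tsv")

    de_mrna = diffexpr.moderated_de(mrna, samples, lfc_min=0.58, alpha=0.05)
    de_mirna = diffexpr.moderated_de(mirna, samples, lfc_min=2.0, alpha=0.05)

    out = args.results / "de"
    out.mkdir(parents=True, exist_ok=True)
    de_mrna.rename_axis("feature_id").to_csv(out / "de_mrna.tsv", sep="\t")
    de_mirna.rename_axis("feature_id").to_csv(out / "de_mirna.tsv", sep="\t")
    for name, de in (("mRNA", de_mrna), ("miRNA", de_mirna)):
        up = int((de["direction"] == "up").sum())
        down = int((de["direction"] == "down").sum())
        print(f"{name}: {up} up + {down} down of {len(de)} features")


if __name__ == "__main__":
    main()
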