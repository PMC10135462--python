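#!/usr/bin/env python
"""Merge-style preprocessing: drop excluded samples, remove batch effects.

Reads results/bundle, removes the additive per-batch offsets with the
two-way (group + batch) linear model, and writes the corrected matrix
plus the retained sample table under results/prep.
"""

import argparse
from pathlib import Path

from cerna_forge import io_prep


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = args.results / "bundle"
    mrna = io_prep.read_expression(bundle / "mrna.tsv")
    mirna = io_prep.read_expression(bundle / "mirna.tsv")
    samples = io_prep.read_sample_table(bundle / "samples.tsv")
    keep = samples.loc[~samples["excluded"].astype(bool), "sample_id"].tolist()
    samples = samples[samples["sample_id"].isin(keep)].reset_index(drop=True)
    mrna = mrna[[s for s in mrna.columns if s in keep]]
    mirna = mirna[[s for s in mirna.columns if s in keep]]
    n_batches = samples["batch"].nunique()
    if n_batches > 1:
        corrected = io_prep.remove_batch_effect(mrna, samples)
    else:
        corrected = mrna

    out = args.results / "prep"
    out.mkdir(parents=True, exist_ok=True)
    io_prep.write_expression(corrected, out / "mrna_corrected.tsv")
    io_prep.write_expression(mirna, out / "mirna.tsv")
    io_prep.write_sample_table(samples, out / "samples.tsv")
    print(f"{len(keep)} samples kept across {n_batches} batches; "
          f"batch component removed from {corrected.shape[0]} genes")


if __name__ == "__main__":
    main()
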