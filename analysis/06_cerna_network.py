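#!/usr/bin/env python
"""ceRNA network construction, hub ranking and direction pruning.

Step 1 keeps miRNA->mRNA target edges whose mRNA is disease-specific
and oppositely regulated to the miRNA (up-mRNA / down-miRNA); step 2
intersects the two miRNA->lncRNA databases; step 3 assembles the
tripartite network over miRNAs with continuous targeting, ranks the
top-15 hubs by degree, and prunes hub lncRNAs whose independent
direction call is not "up".  Outputs land under results/cerna.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from cerna_forge import cerna


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--k", type=int, default=15)
    args = ap.parse_args()

    bundle = args.results / "bundle"
    de_m = pd.read_csv(args.results / "de" / "de_mrna.tsv", sep="\t",
                       index_col="feature_id")
    de_mi = pd.read_csv(args.results / "de" / "de_mirna.tsv", sep="\t",
                        index_col="feature_id")
    specific = pd.read_csv(
        args.results / "wgcna" / "disease_specific_genes.tsv", sep="\t"
    )["gene"].tolist()
    targets = pd.read_csv(bundle / "targets_mrna.tsv", sep="\t")
    db1 = pd.read_csv(bundle / "targets_lnc_db1.tsv", sep="\t")
    db2 = pd.read_csv(bundle / "targets_lnc_db2.tsv", sep="\t")
    directions = pd.read_csv(bundle / "directions.tsv", sep="\t",
                             index_col="node_id")["direction"]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pairs = cerna.build_mrna_mirna_pairs(targets, de_m, de_mi, specific)
        lnc = cerna.consensus_lncrna_pairs(db1, db2, sorted({m for m, _ in pairs}))
        net = cerna.assemble_network(pairs, lnc)
    print(f"step 1: {len(pairs)} mRNA-miRNA pairs; step 2: {len(lnc)} consensus "
          f"miRNA-lncRNA pairs; step 3: network with {net.number_of_nodes()} nodes / "
          f"{net.number_of_edges()} edges")

    out = args.results / "cerna"
    out.mkdir(parents=True, exist_ok=True)
    cerna.write_edge_list(net, out / "network_edges.tsv")
    cerna.write_graphml(net, out / "network.graphml")
    triplets = cerna.enumerate_triplets(net)
    pd.DataFrame([(t.mrna, t.mirna, t.lncrna) for t in triplets],
                 columns=["mrna", "mirna", "lncrna"]) \
        .to_csv(out / "network_triplets.tsv", sep="\t", index=False)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hubs = cerna.rank_hubs(net, args.k)
    pd.DataFrame(hubs.ranked, columns=["node", "degree"]) \
        .to_csv(out / "hubs.tsv", sep="\t", index=False)
    hub_lncs = [n for n, d in hubs.subnetwork.nodes(data=True)
                if d["node_class"] == "lncRNA"]
    dirs = {l: directions.get(l, "ns") for l in hub_lncs}
    pruned, kept = cerna.prune_by_validation(hubs, dirs)
    cerna.write_edge_list(pruned.subnetwork, out / "hub_pruned_edges.tsv")
    pd.DataFrame([(t.mrna, t.mirna, t.lncrna) for t in kept],
                 columns=["mrna", "mirna", "lncrna"]) \
        .to_csv(out / "triplets.tsv", sep="\t", index=False)

    classes = pd.Series(
        {n: d["node_class"] for n, d in pruned.subnetwork.nodes(data=True)}
    ).value_counts().to_dict()
    print(f"hubs (top {args.k} by degree): "
          f"{[n for n, _ in hubs.ranked]}")
    print(f"after direction pruning: {classes}; "
          f"{len(kept)} candidate ceRNA pathways retained")


if __name__ == "__main__":
    main()
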