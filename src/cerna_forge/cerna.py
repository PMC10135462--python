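"""ceRNA (lncRNA-miRNA-mRNA) network construction, hubs and pruning.

Construction follows the three-step recipe: (1) keep miRNA->mRNA target
edges whose mRNA is disease-specific and whose endpoints are
differentially expressed in *opposite* directions (under the default
up-mRNA / down-miRNA polarity, the one the ceRNA hypothesis predicts
when lncRNAs rise); (2) keep miRNA->lncRNA edges present in both of two
prediction databases; (3) assemble the tripartite network from miRNAs
with a "continuous targeting relationship" — at least one retained mRNA
edge and one retained lncRNA edge.

"Negative correlation" between mRNA and miRNA is operationalised as
opposite DE direction, because the mRNA and miRNA profiles typically
come from different cohorts with disjoint samples and cannot be
correlated pairwise; a sample-level Pearson mode is available for
matched designs.

Hubs are the top-k nodes by degree on the full network (ties broken by
node id); pruning then keeps a hub lncRNA only when an independent
direction call (e.g. qRT-PCR) labels it "up", consistent with the
network's up-mRNA / down-miRNA polarity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Triplet",
    "HubSet",
    "canonicalize_mirna",
    "validate_interaction_table",
    "build_mrna_mirna_pairs",
    "consensus_lncrna_pairs",
    "assemble_network",
    "enumerate_triplets",
    "rank_hubs",
    "prune_by_validation",
    "write_edge_list",
    "write_graphml",
]

_MIR_RE = re.compile(r"mir", flags=re.IGNORECASE)


@dataclass(frozen=True, order=True)
class Triplet:
    """One candidate ceRNA regulatory pathway mRNA -- miRNA -- lncRNA."""

    mrna: str
    mirna: str
    lncrna: str


@dataclass
class HubSet:
    """Top-k nodes by degree with the induced hub subnetwork."""

    ranked: list[tuple[str, int]]
    subnetwork: nx.Graph


def canonicalize_mirna(name: str) -> str:
    """Normalise miRNA id casing: trim, rewrite the 'mir' infix to 'miR'.

    Arm suffixes (-3p/-5p) and numbering are preserved; databases in the
    wild disagree on capitalisation ('hsa-mir-455-3p' vs 'hsa-miR-455-3p').
    """
    s = name.strip()
    return _MIR_RE.sub("miR", s, count=1)


def validate_interaction_table(table: pd.DataFrame) -> pd.DataFrame:
    """Canonicalise miRNA ids and enforce edge-list invariants."""
    required = {"mirna_id", "target_id", "target_class"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    t = table.copy()
    t["mirna_id"] = t["mirna_id"].map(canonicalize_mirna)
    t["target_id"] = t["target_id"].astype(str).str.strip()
    if (t["mirna_id"] == "").any() or (t["target_id"] == "").any():
        raise ValueError("empty node id in interaction table")
    bad = set(t["target_class"]) - {"mRNA", "lncRNA"}
    if bad:
        raise ValueError(f"unknown target classes: {sorted(bad)}")
    t = t.drop_duplicates(subset=["mirna_id", "target_id"])
    return t.reset_index(drop=True)


def build_mrna_mirna_pairs(
    targets: pd.DataFrame,
    de_mrna: pd.DataFrame,
    de_mirna: pd.DataFrame,
    specific_mrnas: list[str],
    polarity: str = "up-down-up",
    mrna_expr: pd.DataFrame | None = None,
    mirna_expr: pd.DataFrame | None = None,
    cor_threshold: float = 0.0,
) -> list[tuple[str, str]]:
    """Step 1: miRNA-mRNA pairs over disease-specific, oppositely-DE genes.

    With ``polarity="up-down-up"`` (default) only up-mRNA / down-miRNA
    pairs are kept; ``"down-up-down"`` keeps the mirrored polarity;
    ``"both"`` keeps any opposite-direction pair.  If matched expression
    matrices are supplied, pairs additionally require a sample-level
    Pearson correlation below ``cor_threshold``.
    """
    if polarity not in {"up-down-up", "down-up-down", "both"}:
        raise ValueError(f"unknown polarity {polarity!r}")
    targets = validate_interaction_table(targets)
    targets = targets[targets["target_class"] == "mRNA"]
    if targets.empty:
        warnings.warn("empty miRNA->mRNA target table", stacklevel=2)
        return []
    specific = set(specific_mrnas)
    mdir = de_mrna["direction"]
    midir = de_mirna["direction"]
    pairs = []
    for mir, gene in zip(targets["mirna_id"], targets["target_id"]):
        if gene not in specific or gene not in mdir.index or mir not in midir.index:
            continue
        dg, dm = mdir[gene], midir[mir]
        if dg == "ns" or dm == "ns" or dg == dm:
            continue
        if polarity == "up-down-up" and not (dg == "up" and dm == "down"):
            continue
        if polarity == "down-up-down" and not (dg == "down" and dm == "up"):
            continue
        if mrna_expr is not None and mirna_expr is not None:
            shared = [s for s in mrna_expr.columns if s in mirna_expr.columns]
            r = np.corrcoef(
                mrna_expr.loc[gene, shared], mirna_expr.loc[mir, shared]
            )[0, 1]
            if not r < cor_threshold:
                continue
        pairs.append((mir, gene))
    return sorted(set(pairs))


def consensus_lncrna_pairs(
    db1: pd.DataFrame, db2: pd.DataFrame, mirnas: list[str]
) -> list[tuple[str, str]]:
    """Step 2: miRNA-lncRNA edges present in both prediction databases."""
    keep = set(canonicalize_mirna(m) for m in mirnas)
    sets = []
    for db in (db1, db2):
        t = validate_interaction_table(db)
        t = t[t["target_class"] == "lncRNA"]
        sets.append(set(zip(t["mirna_id"], t["target_id"])))
    consensus = sets[0] & sets[1]
    return sorted((m, l) for m, l in consensus if m in keep)


def assemble_network(
    mrna_pairs: list[tuple[str, str]],
    lncrna_pairs: list[tuple[str, str]],
) -> nx.Graph:
    """Step 3: tripartite network over miRNAs with continuous targeting.

    Only miRNAs appearing in at least one mRNA pair *and* one lncRNA
    pair are retained; mRNAs and lncRNAs whose miRNA partners all
    dropped out disappear with them.  Node attribute ``node_class`` is
    one of mRNA/miRNA/lncRNA; mRNA nodes carry direction "up" and miRNA
    nodes "down" by construction under the default polarity.
    """
    mrna_pairs = sorted(set(mrna_pairs))
    lncrna_pairs = sorted(set(lncrna_pairs))
    mirnas_with_mrna = {m for m, _ in mrna_pairs}
    mirnas_with_lnc = {m for m, _ in lncrna_pairs}
    continuous = mirnas_with_mrna & mirnas_with_lnc
    g = nx.Graph()
    if not continuous:
        warnings.warn("no continuous triplets: empty ceRNA network", stacklevel=2)
        return g
    for mir, gene in mrna_pairs:
        if mir in continuous:
            g.add_node(mir, node_class="miRNA", direction="down")
            g.add_node(gene, node_class="mRNA", direction="up")
            g.add_edge(mir, gene, edge_class="miRNA-mRNA")
    for mir, lnc in lncrna_pairs:
        if mir in continuous:
            g.add_node(mir, node_class="miRNA", direction="down")
            g.add_node(lnc, node_class="lncRNA", direction="unknown")
            g.add_edge(mir, lnc, edge_class="miRNA-lncRNA")
    return g


def enumerate_triplets(net: nx.Graph) -> list[Triplet]:
    """All (mRNA, miRNA, lncRNA) paths through a shared miRNA, sorted."""
    triplets = []
    for mir, data in net.nodes(data=True):
        if data.get("node_class") != "miRNA":
            continue
        neigh = list(net.neighbors(mir))
        mrnas = [n for n in neigh if net.nodes[n]["node_class"] == "mRNA"]
        lncs = [n for n in neigh if net.nodes[n]["node_class"] == "lncRNA"]
        for g_ in mrnas:
            for l in lncs:
                triplets.append(Triplet(g_, mir, l))
    return sorted(triplets)


def rank_hubs(net: nx.Graph, k: int = 15) -> HubSet:
    """Top-k nodes by degree (ties by ascending node id), with subnetwork.

    Degrees are computed on the full network first; the hub subnetwork
    is the induced subgraph on the selected nodes, so its internal
    degrees may be smaller than the ranking degrees.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    degs = sorted(net.degree(), key=lambda kv: (-kv[1], kv[0]))
    if k > len(degs):
        warnings.warn(
            f"k={k} exceeds node count {len(degs)}; returning all nodes", stacklevel=2
        )
        k = len(degs)
    top = degs[:k]
    sub = net.subgraph([n for n, _ in top]).copy()
    return HubSet(ranked=[(n, int(d)) for n, d in top], subnetwork=sub)


def prune_by_validation(
    hubs: HubSet, directions: dict[str, str] | pd.Series
) -> tuple[HubSet, list[Triplet]]:
    """Drop hub lncRNAs whose validated direction is not "up".

    Under the up-mRNA / down-miRNA polarity, a genuine ceRNA partner
    lncRNA must itself be upregulated (it competes for the shared,
    downregulated miRNA).  lncRNAs validated "down" or "ns" are removed
    with their incident edges; nodes left isolated are removed too; the
    surviving triplets are re-enumerated on the pruned subnetwork.
    """
    if isinstance(directions, pd.Series):
        directions = directions.to_dict()
    g = hubs.subnetwork.copy()
    lncs = [n for n, d in g.nodes(data=True) if d.get("node_class") == "lncRNA"]
    missing = [l for l in lncs if l not in directions]
    if missing:
        raise ValueError(f"no validated direction for hub lncRNA(s): {sorted(missing)}")
    drop = [l for l in lncs if directions[l] != "up"]
    g.remove_nodes_from(drop)
    for l in set(lncs) - set(drop):
        g.nodes[l]["direction"] = "up"
    isolated = [n for n, d in g.degree() if d == 0]
    g.remove_nodes_from(isolated)
    ranked = [(n, d) for n, d in hubs.ranked if n in g]
    pruned = HubSet(ranked=ranked, subnetwork=g)
    return pruned, enumerate_triplets(g)


def write_edge_list(net: nx.Graph, path) -> None:
    """Edge-list TSV: node_a, node_b, class_a, class_b (miRNA first)."""
    rows = []
    for a, b in net.edges():
        ca, cb = net.nodes[a]["node_class"], net.nodes[b]["node_class"]
        if cb == "miRNA":
            a, b, ca, cb = b, a, cb, ca
        rows.append((a, b, ca, cb))
    df = pd.DataFrame(sorted(rows), columns=["node_a", "node_b", "class_a", "class_b"])
    df.to_csv(path, sep="\t", index=False)


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
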