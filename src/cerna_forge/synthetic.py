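"""Synthetic cohort generator with planted ground truth.

Emulates the kind of data the pipeline consumes — a merged two-group,
multi-batch log2 microarray cohort plus a small miRNA cohort,
miRNA-target edge tables from several "databases", an independent
direction-validation table (the stand-in for qRT-PCR calls) and immune
signature gene sets — with every recoverable structure planted and
recorded in a :class:`TruthRecord`:

* co-expression modules as latent-factor blocks
  (gene = loading x module eigenvector + Gaussian noise); the first
  ``n_disease_modules`` modules add a case-vs-control shift to their
  eigenvector so they correlate with the trait;
* differentially expressed genes/miRNAs with an explicit +/- log2
  fold-change added to the case group;
* ceRNA triplets with the canonical sign structure (mRNA up, shared
  miRNA down, lncRNA up); triplet mRNAs are planted inside disease
  modules so the intersection funnel recovers them;
* additive per-feature batch offsets, constant within a batch;
* immune gene sets, a subset of which get their members' case means
  raised.

lncRNAs carry no expression matrix — they exist only in interaction
tables and in the direction-validation table, mirroring a design where
lncRNA partners are predicted and validated rather than assayed.

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical parameters and seed give byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cerna_forge.io_prep import (
    make_sample_table,
    write_expression,
    write_sample_table,
)
from cerna_forge.immune import write_gmt

__all__ = [
    "TruthRecord",
    "CohortBundle",
    "generate_cohort",
    "generate_interaction_tables",
    "generate_validation_directions",
    "generate_immune_sets",
    "write_bundle",
]


@dataclass
class TruthRecord:
    """Planted ground truth for one generated cohort bundle."""

    module_membership: dict[str, str] = field(default_factory=dict)  # gene -> module/background
    de_features: dict[str, float] = field(default_factory=dict)  # feature -> signed log2FC
    true_triplets: list[tuple[str, str, str]] = field(default_factory=list)  # (mRNA, miRNA, lncRNA)
    immune_effects: dict[str, float] = field(default_factory=dict)  # shifted set -> shift
    batch_offsets: dict[str, list[float]] = field(default_factory=dict)  # batch -> per-gene offsets
    mrna_ids: list[str] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)
    lncrna_ids: list[str] = field(default_factory=list)
    disease_modules: list[str] = field(default_factory=list)

    def direction_of(self, node: str) -> str:
        """Planted direction of a triplet member or lncRNA."""
        if node in self.lncrna_ids:
            return "up"
        if node in self.de_features:
            return "up" if self.de_features[node] > 0 else "down"
        raise KeyError(f"node {node!r} has no planted direction")

    def validate(self) -> None:
        for mrna, mirna, lnc in self.true_triplets:
            if mrna not in self.mrna_ids:
                raise ValueError(f"triplet mRNA {mrna!r} not in cohort")
            if mirna not in self.mirna_ids:
                raise ValueError(f"triplet miRNA {mirna!r} not in cohort")
            if lnc not in self.lncrna_ids:
                raise ValueError(f"triplet lncRNA {lnc!r} unknown")
            if not self.de_features.get(mrna, 0.0) > 0:
                raise ValueError(f"triplet mRNA {mrna!r} must be planted up")
            if not self.de_features.get(mirna, 0.0) < 0:
                raise ValueError(f"triplet miRNA {mirna!r} must be planted down")


@dataclass
class CohortBundle:
    """Everything one pipeline run needs, with its ground truth."""

    mrna: pd.DataFrame
    mirna: pd.DataFrame
    samples: pd.DataFrame
    truth: TruthRecord
    interactions: list[pd.DataFrame] = field(default_factory=list)
    directions: pd.Series | None = None
    gene_sets: dict[str, list[str]] = field(default_factory=dict)


def _check_positive(**kwargs) -> None:
    for name, v in kwargs.items():
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")


def _simulate_matrix(
    rng, feature_ids, sample_groups, sample_batches, *,
    n_modules, module_size, noise_sd, batch_sd,
    baseline_mean, baseline_sd, module_trait_shift, n_disease_modules,
):
    """Factor-model log2 matrix; returns (values, module labels, batch offsets)."""
    n_feat, n_samp = len(feature_ids), len(sample_groups)
    case = np.asarray([g == "case" for g in sample_groups], dtype=float)
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_feat)
    vals = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_feat, n_samp))
    membership = {}
    module_names = [f"module{m + 1}" for m in range(n_modules)]
    for m in range(n_modules):
        block = slice(m * module_size, (m + 1) * module_size)
        eig = rng.normal(0.0, 1.0, size=n_samp)
        # centre the latent factor within each group so a module carries
        # exactly the trait association it is given, and none by chance
        for gmask in (case == 1.0, case == 0.0):
            if gmask.any():
                eig[gmask] -= eig[gmask].mean()
        if m < n_disease_modules:
            eig = eig + module_trait_shift * case
        loadings = rng.uniform(0.6, 1.0, size=module_size)
        vals[block, :] += loadings[:, None] * eig[None, :]
        for g in feature_ids[block]:
            membership[g] = module_names[m]
    for g in feature_ids[n_modules * module_size:]:
        membership[g] = "background"
    batch_offsets = {}
    batches = pd.unique(pd.Series(sample_batches))
    if len(batches) > 1 and batch_sd > 0:
        for b in batches:
            off = rng.normal(0.0, batch_sd, size=n_feat)
            cols = [i for i, sb in enumerate(sample_batches) if sb == b]
            vals[:, cols] += off[:, None]
            batch_offsets[str(b)] = off.tolist()
    return vals, membership, batch_offsets


def generate_cohort(
    n_control: int = 22,
    n_case: int = 22,
    n_genes: int = 1000,
    n_modules: int = 4,
    module_size: int = 60,
    de_count: int = 60,
    effect_lfc: float = 1.5,
    noise_sd: float = 0.6,
    n_batches: int = 2,
    batch_sd: float = 0.8,
    seed: int = 0,
    *,
    n_mirna: int = 150,
    mirna_de_count: int = 30,
    mirna_effect_lfc: float = 2.5,
    n_triplets: int = 10,
    n_disease_modules: int = 2,
    module_trait_shift: float = 0.8,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
    with_tables: bool = True,
) -> CohortBundle:
    """Generate a planted two-group cohort bundle.

    Positional parameters define the mRNA cohort; keyword extras control
    the companion miRNA cohort, the ceRNA triplets and the disease-module
    trait shift.  ``de_count`` explicit DE genes receive ``+/- effect_lfc``
    in the case group; the first ``n_triplets`` of them are upregulated
    genes inside disease modules and become the planted triplet mRNAs.
    Deterministic given identical parameters and ``seed``.
    """
    _check_positive(n_control=n_control, n_case=n_case, n_genes=n_genes, n_mirna=n_mirna)
    if n_modules < 0 or module_size < 0 or de_count < 0 or n_triplets < 0:
        raise ValueError("counts must be non-negative")
    if effect_lfc < 0 or mirna_effect_lfc < 0 or noise_sd < 0 or batch_sd < 0:
        raise ValueError("effect sizes and standard deviations must be non-negative")
    if n_modules * module_size > n_genes:
        raise ValueError("module_size * n_modules exceeds n_genes")
    if de_count > n_genes:
        raise ValueError("de_count exceeds n_genes")
    if effect_lfc == 0 or mirna_effect_lfc == 0:
        n_triplets = 0  # no valid sign structure to plant
    if n_triplets > 0 and de_count < n_triplets:
        raise ValueError("de_count must cover the planted triplet mRNAs")
    if n_triplets > 0 and (n_modules == 0 or n_disease_modules == 0):
        raise ValueError("triplets require at least one disease module")
    if n_triplets > 0 and mirna_de_count == 0:
        raise ValueError("triplets require planted DE miRNAs")
    if mirna_de_count > n_mirna:
        raise ValueError("mirna_de_count exceeds n_mirna")

    rng = np.random.default_rng(seed)
    n_disease_modules = min(n_disease_modules, n_modules)

    gene_ids = np.array([f"GENE{i + 1:04d}" for i in range(n_genes)])
    mirna_ids = np.array([f"hsa-miR-{100 + i}-5p" for i in range(n_mirna)])
    sample_ids = [f"CTRL{i + 1:02d}" for i in range(n_control)] + [
        f"CASE{i + 1:02d}" for i in range(n_case)
    ]
    groups = ["control"] * n_control + ["case"] * n_case
    # round-robin batches inside each group: balanced, never confounded
    batches = [f"batch{(i % n_batches) + 1}" for i in range(n_control)] + [
        f"batch{(i % n_batches) + 1}" for i in range(n_case)
    ]
    samples = make_sample_table(sample_ids, groups, batches)
    case_mask = np.array([g == "case" for g in groups])

    vals, membership, batch_offsets = _simulate_matrix(
        rng, gene_ids, groups, batches,
        n_modules=n_modules, module_size=module_size, noise_sd=noise_sd,
        batch_sd=batch_sd, baseline_mean=baseline_mean, baseline_sd=baseline_sd,
        module_trait_shift=module_trait_shift, n_disease_modules=n_disease_modules,
    )

    truth = TruthRecord(
        module_membership=membership,
        mrna_ids=gene_ids.tolist(),
        mirna_ids=mirna_ids.tolist(),
        batch_offsets=batch_offsets,
        disease_modules=[f"module{m + 1}" for m in range(n_disease_modules)],
    )

    # explicit DE genes: triplet mRNAs live in disease modules (always up);
    # the rest are drawn from the remaining genes with random signs
    triplet_mrnas: list[str] = []
    if de_count > 0 and effect_lfc > 0:
        if n_triplets > 0:
            disease_gene_pool = [
                g for g in gene_ids if membership[g] in truth.disease_modules
            ]
            triplet_mrnas = [
                str(g)
                for g in rng.choice(disease_gene_pool, size=n_triplets, replace=False)
            ]
        rest_pool = [g for g in gene_ids if g not in set(triplet_mrnas)]
        rest = [
            str(g)
            for g in rng.choice(rest_pool, size=de_count - len(triplet_mrnas), replace=False)
        ]
        for g in triplet_mrnas:
            truth.de_features[g] = effect_lfc
        for g in rest:
            truth.de_features[g] = float(rng.choice([-1.0, 1.0]) * effect_lfc)
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for g in triplet_mrnas + rest:
            vals[gene_pos[g], case_mask] += truth.de_features[g]

    mrna = pd.DataFrame(vals, index=gene_ids, columns=sample_ids)

    # companion miRNA cohort: no module structure, own DE set
    mi_base = rng.normal(baseline_mean - 2.0, baseline_sd, size=n_mirna)
    mi_vals = mi_base[:, None] + rng.normal(
        0.0, noise_sd, size=(n_mirna, len(sample_ids))
    )
    if mirna_de_count > 0 and mirna_effect_lfc > 0:
        de_mi = [str(m) for m in rng.choice(mirna_ids, size=mirna_de_count, replace=False)]
        n_down = (mirna_de_count + 1) // 2
        for i, m in enumerate(de_mi):
            sign = -1.0 if i < n_down else 1.0
            truth.de_features[m] = sign * mirna_effect_lfc
        mi_pos = {m: i for i, m in enumerate(mirna_ids)}
        for m in de_mi:
            mi_vals[mi_pos[m], case_mask] += truth.de_features[m]
        down_mirnas = [m for m in de_mi if truth.de_features[m] < 0]
    else:
        down_mirnas = []
    mirna = pd.DataFrame(mi_vals, index=mirna_ids, columns=sample_ids)

    # planted triplets: distinct combinations over small hub-prone pools
    if n_triplets > 0:
        if not down_mirnas:
            raise ValueError("no downregulated miRNAs available for triplets")
        n_tri_mirna = min(len(down_mirnas), max(3, int(np.ceil(n_triplets / 3))))
        tri_mirnas = down_mirnas[:n_tri_mirna]
        n_tri_lnc = max(3, int(np.ceil(n_triplets / 4)))
        lnc_ids = [f"LNC{i + 1:04d}" for i in range(max(n_tri_lnc, 5))]
        truth.lncrna_ids = lnc_ids
        combos = [
            (g, m, l)
            for g in triplet_mrnas
            for m in tri_mirnas
            for l in lnc_ids[:n_tri_lnc]
        ]
        pick = rng.choice(len(combos), size=n_triplets, replace=False)
        truth.true_triplets = [combos[i] for i in sorted(pick)]
        truth.validate()

    bundle = CohortBundle(mrna=mrna, mirna=mirna, samples=samples, truth=truth)
    if with_tables and n_triplets > 0:
        bundle.interactions = generate_interaction_tables(
            truth, decoy_mrna_edges=200, decoy_lncrna_edges=100,
            db_overlap_fraction=0.3, seed=int(rng.integers(0, 2**31 - 1)),
        )
        bundle.directions = generate_validation_directions(truth)
    if with_tables:
        pool_size = sum(
            1 for g in gene_ids
            if membership[g] == "background" and g not in truth.de_features
        )
        set_size = min(30, pool_size // 5)  # shrink sets for small cohorts
        if set_size >= 5:
            bundle.gene_sets = generate_immune_sets(
                bundle, n_sets=5, set_size=set_size, n_shift_sets=2, shift=1.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
    return bundle


def generate_interaction_tables(
    truth: TruthRecord,
    decoy_mrna_edges: int = 200,
    decoy_lncrna_edges: int = 100,
    db_overlap_fraction: float = 0.3,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Interaction edge tables: one miRNA->mRNA, two miRNA->lncRNA "databases".

    The mRNA table holds every true (miRNA, mRNA) edge plus
    ``decoy_mrna_edges`` random decoys; each lncRNA table holds every
    true (miRNA, lncRNA) edge plus decoys, of which a
    ``db_overlap_fraction`` share is common to both databases — so the
    database intersection always contains exactly the true edges plus
    the shared decoys.
    """
    if not truth.true_triplets:
        raise ValueError("truth has no planted triplets")
    if not 0 <= db_overlap_fraction <= 1:
        raise ValueError("db_overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    true_mrna_edges = sorted({(m, g) for g, m, _ in truth.true_triplets})
    true_lnc_edges = sorted({(m, l) for _, m, l in truth.true_triplets})

    def _decoys(n, mirna_pool, target_pool, forbidden):
        out = set()
        attempts = 0
        while len(out) < n and attempts < 50 * max(n, 1) + 1000:
            m = mirna_pool[rng.integers(0, len(mirna_pool))]
            t = target_pool[rng.integers(0, len(target_pool))]
            if (m, t) not in forbidden and (m, t) not in out:
                out.add((m, t))
            attempts += 1
        if len(out) < n:
            raise ValueError("could not place the requested number of decoy edges")
        return sorted(out)

    forbidden_m = set(true_mrna_edges)
    mrna_decoys = _decoys(decoy_mrna_edges, truth.mirna_ids, truth.mrna_ids, forbidden_m)
    mrna_table = pd.DataFrame(
        [(m, g, "mRNA") for m, g in true_mrna_edges + mrna_decoys],
        columns=["mirna_id", "target_id", "target_class"],
    )
    mrna_table["source_db"] = "synthetic_targetdb"

    # decoy lncRNA pool: extend beyond the true lncRNAs so decoys exist
    lnc_pool = list(truth.lncrna_ids) + [
        f"DECOYLNC{i + 1:04d}" for i in range(max(20, decoy_lncrna_edges // 2))
    ]
    forbidden_l = set(true_lnc_edges)
    n_shared = int(round(db_overlap_fraction * decoy_lncrna_edges))
    shared = _decoys(n_shared, truth.mirna_ids, lnc_pool, forbidden_l)
    taken = forbidden_l | set(shared)
    own1 = _decoys(decoy_lncrna_edges - n_shared, truth.mirna_ids, lnc_pool, taken)
    taken |= set(own1)
    own2 = _decoys(decoy_lncrna_edges - n_shared, truth.mirna_ids, lnc_pool, taken)

    def _lnc_table(own, name):
        edges = true_lnc_edges + shared + own
        t = pd.DataFrame(
            [(m, l, "lncRNA") for m, l in sorted(set(edges))],
            columns=["mirna_id", "target_id", "target_class"],
        )
        t["source_db"] = name
        return t

    return [
        mrna_table,
        _lnc_table(own1, "synthetic_lncdb1"),
        _lnc_table(own2, "synthetic_lncdb2"),
    ]


def generate_validation_directions(
    truth: TruthRecord,
    flip_ids: list[str] = (),
    ns_ids: list[str] = (),
) -> pd.Series:
    """Direction-validation table (the qRT-PCR stand-in).

    Every node with a planted direction gets it, except ids in
    ``flip_ids`` (direction reversed) and ``ns_ids`` (labelled "ns").
    """
    flip, ns = set(flip_ids), set(ns_ids)
    if flip & ns:
        raise ValueError(f"ids in both flip and ns lists: {sorted(flip & ns)}")
    nodes: list[str] = []
    for g, m, l in truth.true_triplets:
        for node in (g, m, l):
            if node not in nodes:
                nodes.append(node)
    for l in truth.lncrna_ids:
        if l not in nodes:
            nodes.append(l)
    known = set(nodes) | set(truth.de_features)
    unknown = (flip | ns) - known
    if unknown:
        raise KeyError(f"ids not in truth: {sorted(unknown)}")
    out = {}
    for node in nodes:
        d = truth.direction_of(node)
        if node in flip:
            d = {"up": "down", "down": "up"}[d]
        if node in ns:
            d = "ns"
        out[node] = d
    return pd.Series(out, name="direction")


def generate_immune_sets(
    bundle: CohortBundle,
    n_sets: int = 5,
    set_size: int = 30,
    n_shift_sets: int = 2,
    shift: float = 1.0,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Immune signature sets; the first ``n_shift_sets`` are planted.

    Members are drawn (without replacement across sets) from background,
    non-DE cohort genes; planted sets get their members' case-group
    means raised by ``shift`` in the bundle's mRNA matrix, and the truth
    records which sets were shifted.  ``shift = 0`` plants nothing.
    """
    if n_shift_sets > n_sets:
        raise ValueError("n_shift_sets exceeds n_sets")
    _check_positive(n_sets=n_sets, set_size=set_size)
    truth = bundle.truth
    pool = [
        g for g in bundle.mrna.index
        if truth.module_membership.get(g) == "background" and g not in truth.de_features
    ]
    if n_sets * set_size > len(pool):
        raise ValueError(
            f"need {n_sets * set_size} background genes for the sets, have {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n_sets * set_size, replace=False)
    case_cols = bundle.samples.loc[
        bundle.samples["group"] == "case", "sample_id"
    ].tolist()
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        name = f"immune_set_{i + 1}"
        members = sorted(chosen[i * set_size : (i + 1) * set_size])
        sets[name] = members
        if i < n_shift_sets and shift != 0:
            bundle.mrna.loc[members, case_cols] += shift
            truth.immune_effects[name] = shift
    bundle.gene_sets = sets
    return sets


def write_bundle(bundle: CohortBundle, out_dir) -> Path:
    """Write the bundle directory the pipeline can be run from."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.mrna, out / "mrna.tsv")
    write_expression(bundle.mirna, out / "mirna.tsv")
    write_sample_table(bundle.samples, out / "samples.tsv")
    names = ["targets_mrna.tsv", "targets_lnc_db1.tsv", "targets_lnc_db2.tsv"]
    for tbl, name in zip(bundle.interactions, names):
        tbl.to_csv(out / name, sep="\t", index=False)
    if bundle.directions is not None:
        bundle.directions.rename_axis("node_id").reset_index().to_csv(
            out / "directions.tsv", sep="\t", index=False
        )
    if bundle.gene_sets:
        write_gmt(bundle.gene_sets, out / "immune_sets.gmt")
    with open(out / "truth.json", "wt", encoding="utf-8") as fh:
        json.dump(asdict(bundle.truth), fh, indent=1)
    return out
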