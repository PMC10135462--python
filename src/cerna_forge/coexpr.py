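"""Weighted co-expression network analysis: soft threshold, TOM, modules.

The network is unsigned: adjacency ``a_ij = |cor(i, j)|^beta`` with
Pearson correlation.  Topological overlap between genes i != j is

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with ``a_ii = 0`` in the connectivity ``k_i = sum_{j != i} a_ij`` and
``TOM_ii = 1``.  Genes are clustered by average linkage on ``1 - TOM``;
modules come from a static cut of the dendrogram (default at the 0.99
quantile of merge heights), clusters below the minimum size fall into
the unassigned "grey" bin, and modules whose eigengenes are closer than
the merge cut height (1 - correlation) are merged iteratively.

Module labels follow the conventional colour sequence (turquoise, blue,
brown, ... by decreasing size); "grey" is always the unassigned label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

__all__ = [
    "SoftThresholdReport",
    "ModuleAssignment",
    "select_top_variance",
    "detect_outlier_samples",
    "pick_soft_threshold",
    "adjacency_matrix",
    "compute_tom",
    "detect_modules",
    "module_trait",
    "gene_stats",
    "disease_specific_genes",
    "MODULE_COLORS",
]

GREY = "grey"

#: colour sequence for module labels, ordered by module size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
]


@dataclass
class SoftThresholdReport:
    """Scale-free-fit diagnostics for each candidate soft power."""

    table: pd.DataFrame  # columns: power, r2_signed, mean_k, median_k, max_k
    selected: int
    r2_target: float
    target_met: bool


@dataclass
class ModuleAssignment:
    """Gene -> module labels plus eigengene-level statistics."""

    modules: pd.Series  # gene -> colour label ("grey" = unassigned)
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x sample
    mm: pd.DataFrame | None = None  # gene x module correlations
    gs: pd.Series | None = None  # gene -> trait correlation

    @property
    def module_labels(self) -> list[str]:
        return [m for m in self.eigengenes.index] if len(self.eigengenes) else sorted(
            set(self.modules) - {GREY}
        )


def select_top_variance(x: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Keep the ``ceil(fraction * n)`` most variable features.

    Ties at the cut are broken by ascending feature id so the selection
    is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return x.copy()
    n_keep = int(np.ceil(fraction * x.shape[0]))
    v = x.var(axis=1, ddof=1)
    order = sorted(x.index, key=lambda g: (-v[g], g))
    keep = sorted(order[:n_keep])
    return x.loc[keep]


def detect_outlier_samples(x: pd.DataFrame, cut_height: float) -> list[str]:
    """Flag samples that split off the main cluster above ``cut_height``.

    Average-linkage hierarchical clustering on Euclidean distances
    between sample expression profiles; the largest cluster obtained by
    cutting the tree at ``cut_height`` is kept, everything else flagged.
    """
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    profiles = x.to_numpy(dtype=float).T
    link = hierarchy.linkage(profiles, method="average", metric="euclidean")
    if not np.isfinite(cut_height):
        return []
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    counts = pd.Series(labels).value_counts()
    main = counts.idxmax()
    return [s for s, lab in zip(x.columns, labels) if lab != main]


def adjacency_matrix(x: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned adjacency ``|cor|^beta`` with zero diagonal."""
    vals = x.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = x.index[sd == 0][0]
        raise ValueError(f"zero-variance gene: {bad}")
    cor = np.corrcoef(vals)
    a = np.abs(np.clip(cor, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 density(k) vs log10 k over equal-count bins.

    Positive when the log-log slope is negative (the scale-free
    direction); returns the fit for however many (>=2) occupied bins
    survive de-duplication of quantile edges.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        raise ValueError("fewer than 2 positive connectivities")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        # degenerate spread: treat distinct k values as their own bins
        uniq, counts = np.unique(k, return_counts=True)
        if uniq.size < 2:
            raise ValueError("fewer than 2 occupied connectivity bins")
        xs, ys = [], []
        width = np.min(np.diff(uniq))
        for u, c in zip(uniq, counts):
            xs.append(np.log10(u))
            ys.append(np.log10(c / (k.size * width)))
        xs, ys = np.array(xs), np.array(ys)
    else:
        idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
        xs, ys = [], []
        for b in range(edges.size - 1):
            sel = idx == b
            if not sel.any():
                continue
            width = edges[b + 1] - edges[b]
            if width <= 0:
                continue
            xs.append(np.log10(np.mean(k[sel])))
            ys.append(np.log10(sel.sum() / (k.size * width)))
        xs, ys = np.array(xs), np.array(ys)
        if xs.size < 2:
            raise ValueError("fewer than 2 occupied connectivity bins")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def _default_power_for(n_samples: int) -> int:
    """Conventional unsigned-network soft power by sample size."""
    if n_samples < 20:
        return 9
    if n_samples < 30:
        return 8
    if n_samples < 40:
        return 7
    return 6


def pick_soft_threshold(
    x: pd.DataFrame,
    powers=tuple(range(1, 13)),
    r2_target: float = 0.85,
    fallback: str = "max_r2",
) -> SoftThresholdReport:
    """Scan candidate soft powers for approximate scale-free topology.

    Selects the smallest power whose signed scale-free R^2 reaches
    ``r2_target``.  If none does, a warning is emitted and the fallback
    rule applies: ``"max_r2"`` takes the power with the maximal R^2
    (which on clearly non-scale-free data tends to be the largest power
    tested), while ``"sample-size"`` takes the conventional
    unsigned-network default for the cohort's sample count (9 below 20
    samples, 8 below 30, 7 below 40, 6 otherwise), clipped to the
    tested grid.
    """
    powers = list(powers)
    if not powers:
        raise ValueError("powers must be non-empty")
    if fallback not in {"max_r2", "sample-size"}:
        raise ValueError("fallback must be 'max_r2' or 'sample-size'")
    rows = []
    for beta in powers:
        a = adjacency_matrix(x, beta)
        k = a.sum(axis=0)
        try:
            r2 = _scale_free_fit(k)
        except ValueError:
            r2 = np.nan
        rows.append(
            {
                "power": beta,
                "r2_signed": r2,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["r2_signed"] >= r2_target]
    if len(ok):
        selected = int(ok.iloc[0]["power"])
        met = True
    else:
        met = False
        if fallback == "max_r2":
            selected = int(table.loc[table["r2_signed"].idxmax(), "power"])
            how = "max R^2"
        else:
            wanted = _default_power_for(x.shape[1])
            selected = int(min(powers, key=lambda b: abs(b - wanted)))
            how = f"sample-size default for {x.shape[1]} samples"
        warnings.warn(
            f"no power reached scale-free R^2 >= {r2_target}; "
            f"falling back to beta={selected} ({how})",
            stacklevel=2,
        )
    return SoftThresholdReport(table=table, selected=selected, r2_target=r2_target, target_met=met)


def compute_tom(x: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Topological overlap matrix of the unsigned ``|cor|^beta`` network."""
    if x.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    a = adjacency_matrix(x, beta)
    return tom_from_adjacency(a, index=x.index)


def tom_from_adjacency(a: np.ndarray, index=None) -> pd.DataFrame:
    """TOM from a zero-diagonal adjacency matrix (vectorised)."""
    a = np.asarray(a, dtype=float)
    k = a.sum(axis=0)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if index is None:
        index = pd.RangeIndex(a.shape[0])
    return pd.DataFrame(tom, index=index, columns=index)


def _eigengene(x_mod: pd.DataFrame) -> np.ndarray:
    """First principal component of a module, as a unit-norm sample vector.

    Genes are standardised across samples first; the sign is oriented so
    the eigengene correlates positively with the module mean profile.
    """
    vals = x_mod.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    # first right singular vector = PC scores over samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    return me


def _persistent_branches(
    link: np.ndarray, min_size: int, min_persistence_frac: float
) -> list[list[int]]:
    """Select tree branches that persist over a wide height interval.

    A branch born at its own merge height and absorbed at its parent's
    merge height is a module candidate when it holds at least
    ``min_size`` leaves and survives for at least
    ``min_persistence_frac`` of the tree's total merge-height range.
    Real co-expression modules coalesce low and are only absorbed near
    the top of the tree, while unstructured background genes chain
    together in closely spaced merges, so their branches die almost
    immediately.  Candidates are taken greedily by descending
    persistence, skipping any branch overlapping an already selected
    one; the root is never a candidate (a "module" spanning every gene
    is indistinguishable from an unstructured matrix).  Returns
    ``(core_members, all_members)`` index pairs per branch: the core is
    the branch at birth, ``all_members`` additionally holds everything
    absorbed before death.
    """
    n = link.shape[0] + 1
    heights = link[:, 2]
    h_range = float(heights.max() - heights.min()) if n > 1 else 0.0
    thr = min_persistence_frac * h_range
    members: list[list[int] | None] = [[i] for i in range(n)] + [None] * (n - 1)
    birth: list[float | None] = [None] * (2 * n - 1)
    core: list[list[int] | None] = [None] * (2 * n - 1)  # members at branch birth
    recorded: list[tuple[float, int, list[int], list[int]]] = []
    for j in range(n - 1):
        a, b = int(link[j, 0]), int(link[j, 1])
        h = float(heights[j])
        node = n + j
        sa, sb = len(members[a]), len(members[b])
        members[node] = members[a] + members[b]
        if sa >= min_size and sb >= min_size:
            # a genuine merge of two branches: both die here, a new one is born
            for child in (a, b):
                if birth[child] is not None and h - birth[child] > thr:
                    recorded.append(
                        (h - birth[child], len(members[child]), core[child], members[child])
                    )
            birth[node] = h
            core[node] = members[node]
        elif sa >= min_size:
            birth[node] = birth[a]  # branch continues through a small absorption
            core[node] = core[a]
        elif sb >= min_size:
            birth[node] = birth[b]
            core[node] = core[b]
        elif sa + sb >= min_size:
            birth[node] = h  # a chain of small pieces just crossed the size bar
            core[node] = members[node]
    # a branch that survives to the root (absorbing only small pieces on
    # the way) dies at the final merge height; it is recorded under the
    # same persistence rule, so an unstructured near-root chain never
    # qualifies but a single dominant module does
    root = 2 * n - 2
    if n > 1 and birth[root] is not None:
        h_top = float(heights[-1])
        if h_top - birth[root] > thr:
            recorded.append((h_top - birth[root], n, core[root], members[root]))
    recorded.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    used = np.zeros(n, dtype=bool)
    out = []
    for _, _, core_mem, all_mem in recorded:
        if used[all_mem].any():
            continue
        used[all_mem] = True
        out.append((sorted(core_mem), sorted(all_mem)))
    return out


def detect_modules(
    tom: pd.DataFrame,
    x: pd.DataFrame,
    min_module_size: int = 50,
    merge_cut_height: float = 0.15,
    cut_height: float | None = None,
    min_persistence_frac: float = 0.05,
    min_kme: float = 0.5,
) -> ModuleAssignment:
    """Tree-cut module detection on ``1 - TOM`` with eigengene merging.

    Average-linkage clustering of ``1 - TOM``; modules are branches
    selected by the persistence rule of :func:`_persistent_branches`
    (or, when an explicit ``cut_height`` is given, by a static cut at
    that height followed by the minimum-size filter).  Genes a branch
    absorbed after its birth are kept only when their correlation with
    the branch-core eigengene reaches ``min_kme`` (the standard module
    membership filter), so late background stragglers fall back to
    grey.  Clusters smaller than ``min_module_size`` are grey; modules
    whose eigengene dissimilarity ``1 - cor(ME_a, ME_b)`` falls below
    ``merge_cut_height`` are merged until no such pair remains.  Labels
    are colours ordered by final module size.
    """
    genes = list(tom.index)
    if list(x.index) != genes:
        x = x.loc[genes]
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    link = hierarchy.linkage(condensed, method="average")

    groups: dict[int, list[str]] = {}
    if cut_height is not None:
        raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
        labels = pd.Series(raw, index=genes)
        counts = labels.value_counts()
        for c, size in counts.items():
            if size >= min_module_size:
                groups[int(c)] = [g for g in genes if labels[g] == c]
    else:
        branches = _persistent_branches(link, min_module_size, min_persistence_frac)
        for c, (core_mem, all_mem) in enumerate(branches, start=1):
            core_genes = [genes[i] for i in core_mem]
            me = _eigengene(x.loc[core_genes])
            core_set = set(core_mem)
            kept = list(core_genes)
            for i in all_mem:
                if i in core_set:
                    continue
                g = genes[i]
                if abs(_pearson(x.loc[g].to_numpy(dtype=float), me)) >= min_kme:
                    kept.append(g)
            if len(kept) >= min_module_size:
                groups[c] = kept

    if not groups:
        warnings.warn("all genes unassigned (grey); no modules detected", stacklevel=2)
        return ModuleAssignment(
            modules=pd.Series(GREY, index=genes),
            eigengenes=pd.DataFrame(columns=x.columns),
        )
    mes = {c: _eigengene(x.loc[gl]) for c, gl in groups.items()}

    # iterative eigengene merging: closest pair first
    while len(groups) > 1:
        ids = sorted(groups)
        me_mat = np.vstack([mes[c] for c in ids])
        cor = np.corrcoef(me_mat)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_cut_height:
            break
        a, b = ids[i], ids[j]
        groups[a] = groups[a] + groups[b]
        del groups[b]
        mes[a] = _eigengene(x.loc[groups[a]])
        del mes[b]

    ordered = sorted(groups, key=lambda c: (-len(groups[c]), c))
    color_of = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(ordered)}
    modules = pd.Series(GREY, index=genes, dtype=object)
    for c, gl in groups.items():
        modules[gl] = color_of[c]
    eigengenes = pd.DataFrame(
        {color_of[c]: mes[c] for c in ordered}, index=x.columns
    ).T
    return ModuleAssignment(modules=modules, eigengenes=eigengenes)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def _cor_test_p(r: float, n: int) -> float:
    if n <= 2 or abs(r) >= 1:
        return 0.0 if abs(r) >= 1 and n > 2 else 1.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def module_trait(assign: ModuleAssignment, samples: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with the case trait.

    The trait is encoded control=0 / case=1, so positive r means
    disease-associated; p comes from ``t = r sqrt((n-2)/(1-r^2))`` on
    ``n - 2`` degrees of freedom.  Constant eigengenes get r = 0 and a
    ``degenerate`` flag.
    """
    t = samples.set_index("sample_id")
    trait = np.array(
        [1.0 if t.loc[s, "group"] == "case" else 0.0 for s in assign.eigengenes.columns]
    )
    n = trait.size
    rows = []
    for mod in assign.eigengenes.index:
        me = assign.eigengenes.loc[mod].to_numpy(dtype=float)
        degenerate = me.std() == 0 or trait.std() == 0
        r = _pearson(me, trait)
        rows.append(
            {
                "module": mod,
                "r": r,
                "p": _cor_test_p(r, n) if not degenerate else 1.0,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("module")


def gene_stats(
    assign: ModuleAssignment, x: pd.DataFrame, samples: pd.DataFrame
) -> ModuleAssignment:
    """Attach module membership (MM) and gene significance (GS).

    MM is the gene-eigengene Pearson correlation (gene x module matrix);
    GS is the gene-trait Pearson correlation with control=0 / case=1.
    """
    if assign.eigengenes.empty:
        raise ValueError("eigengenes not computed")
    t = samples.set_index("sample_id")
    cols = list(assign.eigengenes.columns)
    xs = x[cols]
    trait = np.array([1.0 if t.loc[s, "group"] == "case" else 0.0 for s in cols])
    vals = xs.to_numpy(dtype=float)
    mm = pd.DataFrame(index=xs.index, columns=assign.eigengenes.index, dtype=float)
    for mod in assign.eigengenes.index:
        me = assign.eigengenes.loc[mod].to_numpy(dtype=float)
        mm[mod] = [_pearson(v, me) for v in vals]
    gs = pd.Series([_pearson(v, trait) for v in vals], index=xs.index, name="GS")
    assign.mm = mm
    assign.gs = gs
    return assign


def disease_specific_genes(
    de: pd.DataFrame, assign: ModuleAssignment, modules: list[str]
) -> list[str]:
    """DE features that also belong to the selected modules, sorted.

    Mirrors the funnel step that intersects the differential-expression
    hits with the genes of the disease-associated modules.
    """
    known = set(assign.modules.unique())
    unknown = [m for m in modules if m not in known]
    if unknown:
        raise ValueError(f"unknown module labels: {unknown}")
    in_mod = set(assign.modules[assign.modules.isin(modules)].index)
    hits = set(de.index[de["direction"] != "ns"])
    return sorted(in_mod & hits)
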