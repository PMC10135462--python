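"""Immune-infiltration scoring (ssGSEA) and hub-gene correlation.

Each immune cell type is represented by a signature gene set; ssGSEA
scores one sample at a time: genes are ranked by expression (descending,
average ranks for ties), the in-set empirical distribution is
accumulated with weights ``rank^alpha`` (alpha = 0.25 by default) while
out-of-set genes accumulate uniformly, and the score is the sum of the
running difference between the two distributions over the whole ranked
list.  Scores are min-max normalised across the full matrix by default.
Because only ranks enter, scores are invariant to any strictly monotone
transform of a sample's expression values.

Hub genes are related to cell-type scores by Spearman correlation
(tie-corrected ranks, p from the t approximation on n-2 df; exact
permutation available for small n), and case/control score differences
are tested with the two-sided Mann-Whitney U test (exact enumeration
for small groups, normal approximation with tie correction otherwise).
"""

from __future__ import annotations

import itertools
import warnings
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "read_gmt",
    "write_gmt",
    "ssgsea_scores",
    "ssgsea_sample",
    "spearman_corr",
    "correlate_hub_scores",
    "mann_whitney",
    "compare_groups",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, list[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 fields")
            name, members = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            if not members:
                raise ValueError(f"{path}: line {lineno}: empty gene set {name!r}")
            sets[name] = members
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write(name + "\t" + description + "\t" + "\t".join(members) + "\n")


def ssgsea_sample(expr: np.ndarray, in_set: np.ndarray, alpha: float = 0.25) -> float:
    """ssGSEA running-sum score for one sample.

    ``expr`` is the sample's expression over all genes, ``in_set`` a
    boolean membership mask.  Ranks are ascending with average ties, so
    the most expressed gene carries the largest weight ``rank^alpha``.
    """
    n = expr.size
    n_in = int(in_set.sum())
    if n_in == 0 or n_in == n:
        raise ValueError("gene set must be a proper, non-empty subset")
    ranks = rankdata(expr)  # average ties
    order = np.argsort(-expr, kind="stable")
    w = np.abs(ranks[order]) ** alpha
    mask = in_set[order]
    w_in = np.where(mask, w, 0.0)
    sum_w_in = w_in.sum()
    p_in = np.cumsum(w_in) / sum_w_in
    p_out = np.cumsum(np.where(mask, 0.0, 1.0)) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    x: pd.DataFrame,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA score matrix, gene sets x samples.

    Sets with no member present in the matrix raise; sets with under a
    quarter of their members present trigger a warning but are scored
    on the present members.  With ``normalize=True`` all scores are
    min-max scaled to [0, 1] across the entire matrix.
    """
    genes = list(x.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    masks = {}
    for name, members in sets.items():
        present = [g for g in members if g in gene_pos]
        if not present:
            raise ValueError(f"gene set {name!r} has no member in the matrix")
        if len(present) < 0.25 * len(members):
            warnings.warn(
                f"gene set {name!r}: only {len(present)}/{len(members)} members present",
                stacklevel=2,
            )
        mask = np.zeros(len(genes), dtype=bool)
        mask[[gene_pos[g] for g in present]] = True
        masks[name] = mask
    vals = x.to_numpy(dtype=float)
    out = pd.DataFrame(index=list(sets), columns=x.columns, dtype=float)
    for s_idx, sample in enumerate(x.columns):
        expr = vals[:, s_idx]
        for name, mask in masks.items():
            out.loc[name, sample] = ssgsea_sample(expr, mask, alpha=alpha)
    if normalize:
        lo, hi = out.min().min(), out.max().max()
        if hi > lo:
            out = (out - lo) / (hi - lo)
        else:
            out = out * 0.0
    out.attrs["method"] = "ssgsea"
    out.attrs["alpha"] = alpha
    return out


def spearman_corr(u, v, exact_max_n: int = 0) -> tuple[float, float, bool]:
    """Tie-corrected Spearman rho with a t-approximation p-value.

    Returns ``(rho, p, degenerate)``; a constant input yields rho = 0
    with the degenerate flag set.  When ``n <= exact_max_n`` the p-value
    is computed by exact permutation of one ranking instead.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    n = u.size
    if np.std(u) == 0 or np.std(v) == 0:
        return 0.0, 1.0, True
    ru, rv = rankdata(u), rankdata(v)
    rho = float(np.corrcoef(ru, rv)[0, 1])
    if n <= exact_max_n:
        observed = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(ru[list(perm)], rv)[0, 1]
            count += abs(r) >= observed - 1e-12
            total += 1
        return rho, count / total, False
    if abs(rho) >= 1.0:
        return rho, 0.0, False
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p, False


def correlate_hub_scores(
    x: pd.DataFrame, hub_mrnas: list[str], scores: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of each hub gene with each cell-type score."""
    missing = [g for g in hub_mrnas if g not in x.index]
    if missing:
        raise ValueError(f"hub genes absent from expression matrix: {missing}")
    shared = [s for s in x.columns if s in scores.columns]
    rows = []
    for gene in hub_mrnas:
        gv = x.loc[gene, shared].to_numpy(dtype=float)
        for cell in scores.index:
            sv = scores.loc[cell, shared].to_numpy(dtype=float)
            rho, p, degenerate = spearman_corr(gv, sv)
            rows.append(
                {"gene": gene, "cell_type": cell, "rho": rho, "p": p, "degenerate": degenerate}
            )
    return pd.DataFrame(rows)


def mann_whitney(a, b, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (min-U convention) and p-value.

    Exact p by enumerating all arrangements of the pooled ranks when
    both groups have at most ``exact_max_n`` observations; otherwise the
    normal approximation with tie correction (and 0.5 continuity
    correction) is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    if max(n1, n2) <= exact_max_n:
        # enumerate which pooled positions belong to group a
        count = 0
        total = comb(n1 + n2, n1)
        for combo in itertools.combinations(range(n1 + n2), n1):
            r = ranks[list(combo)].sum()
            u1_perm = r - n1 * (n1 + 1) / 2.0
            u_perm = min(u1_perm, n1 * n2 - u1_perm)
            count += u_perm <= u + 1e-12
        return float(u), count / total
    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u), 1.0
    mu = n1 * n2 / 2.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    return float(u), float(2.0 * stats.norm.sf(z))


def compare_groups(scores: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney case-vs-control comparison per cell type."""
    t = samples.set_index("sample_id")
    case = [s for s in scores.columns if t.loc[s, "group"] == "case"]
    ctrl = [s for s in scores.columns if t.loc[s, "group"] == "control"]
    if not case or not ctrl:
        raise ValueError("both groups must be represented in the score matrix")
    rows = []
    for cell in scores.index:
        u, p = mann_whitney(
            scores.loc[cell, case].to_numpy(dtype=float),
            scores.loc[cell, ctrl].to_numpy(dtype=float),
        )
        delta = float(
            scores.loc[cell, case].median() - scores.loc[cell, ctrl].median()
        )
        rows.append({"cell_type": cell, "U": u, "p": p, "median_shift": delta})
    return pd.DataFrame(rows)
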