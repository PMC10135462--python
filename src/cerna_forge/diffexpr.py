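"""Two-group differential expression with empirical-Bayes moderation.

Per feature g the pooled two-sample variance ``s2_g`` (``d_g = n - 2``
degrees of freedom) is shrunk toward a prior ``(d0, s0^2)`` estimated by
moment matching on ``log s2_g``, giving the moderated variance

    s2_tilde = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated t statistic ``t = log2FC / (s_tilde * sqrt(1/n1 + 1/n2))``
on ``d0 + d_g`` degrees of freedom.  With ``d0 = 0`` the statistic reduces
to the ordinary pooled-variance t; with ``d0 = inf`` the prior dominates
and p-values come from the normal limit.

``log2FC`` is always case mean minus control mean, so "up" means higher
in the disease group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = ["moderated_de", "bh_adjust", "apply_thresholds", "fit_variance_prior"]

#: default fold-change cutoffs printed by the study: mRNA |log2FC| > 0.58,
#: miRNA |log2FC| > 2, both at BH-adjusted p < 0.05
MRNA_LFC_MIN = 0.58
MIRNA_LFC_MIN = 2.0
DEFAULT_ALPHA = 0.05


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Works on ``z = log s2``, whose mean and variance under the hierarchical
    model are known in terms of digamma/trigamma functions; returns
    ``(d0, s0_squared)`` with ``d0 = inf`` when the observed spread of
    ``z`` is no larger than the within-feature sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def moderated_de(
    x: pd.DataFrame,
    samples: pd.DataFrame,
    lfc_min: float = MRNA_LFC_MIN,
    alpha: float = DEFAULT_ALPHA,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression, case vs. control.

    Parameters
    ----------
    x : features x samples log2 expression matrix.
    samples : sample table with ``sample_id`` and ``group`` columns.
    lfc_min, alpha : threshold rule applied to fill the ``direction``
        column (strict inequalities; see :func:`apply_thresholds`).
    prior_df : force the prior degrees of freedom ``d0`` instead of
        estimating them (``0`` recovers the ordinary pooled t).

    Returns
    -------
    DataFrame indexed by feature id, sorted by feature id, with columns
    ``log2FC, t_mod, p_raw, p_adj, direction, degenerate``.
    """
    t = samples.set_index("sample_id")
    case_ids = [s for s in x.columns if t.loc[s, "group"] == "case"]
    ctrl_ids = [s for s in x.columns if t.loc[s, "group"] == "control"]
    n1, n2 = len(case_ids), len(ctrl_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    vals = x.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("missing or non-finite values in expression matrix")
    yc = x[case_ids].to_numpy(dtype=float)
    y0 = x[ctrl_ids].to_numpy(dtype=float)
    lfc = yc.mean(axis=1) - y0.mean(axis=1)
    ss = ((yc - yc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y0 - y0.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    dg = n1 + n2 - 2
    s2 = ss / dg
    degenerate = s2 <= 0

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2[~degenerate], dg)
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2[~degenerate], dg) if d0 > 0 else (None, 1.0)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = dg
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.sign(lfc) * np.inf)
    t_mod = np.where((se == 0) & (lfc == 0), 0.0, t_mod)
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_raw = np.where(np.isinf(t_mod), 0.0, p_raw)

    out = pd.DataFrame(
        {
            "log2FC": lfc,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "degenerate": degenerate | (se == 0),
        },
        index=x.index,
    )
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out = out.sort_index()
    out = apply_thresholds(out, lfc_min=lfc_min, alpha=alpha)
    return out[["log2FC", "t_mod", "p_raw", "p_adj", "direction", "degenerate"]]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the ascending-sorted vector,
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def apply_thresholds(table: pd.DataFrame, lfc_min: float, alpha: float) -> pd.DataFrame:
    """Fill the ``direction`` column by the strict threshold rule.

    up:   log2FC >  lfc_min and p_adj < alpha
    down: log2FC < -lfc_min and p_adj < alpha
    ns:   otherwise (boundary values are ns — the cutoffs are strict).
    """
    if lfc_min <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    out = table.copy()
    up = (out["log2FC"] > lfc_min) & (out["p_adj"] < alpha)
    down = (out["log2FC"] < -lfc_min) & (out["p_adj"] < alpha)
    out["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out
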