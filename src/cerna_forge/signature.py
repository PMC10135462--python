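"""Diagnostic signature: LASSO feature selection + random-forest model.

Candidate genes (the disease-specific DE set) are filtered by
L1-penalised logistic regression — features keeping a nonzero
coefficient at the cross-validated penalty are retained — and the
retained genes parameterise a bagged-trees model fit as *regression* on
the 0/1 group response, so both of the conventional importance measures
(%IncMSE, out-of-bag permutation; IncNodePurity, total impurity
decrease) are defined.  Performance is summarised by the rank-based AUC
(AUC = U / (n1 * n2), ties counted 1/2) on a stratified train/validation
split, by stratified k-fold cross-validation with the whole selection +
fit pipeline re-run inside each fold, and optionally on an external
cohort.

The L1 path solver is glmnet-style: iteratively reweighted least
squares with cyclic coordinate descent on the penalised weighted
quadratic approximation, warm-started along a geometric lambda grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "SignatureModel",
    "RocResult",
    "split_train_validation",
    "lasso_select",
    "lasso_path_logistic",
    "rf_fit_and_importance",
    "predict_scores",
    "evaluate_roc",
    "auc_score",
    "roc_curve_points",
    "cross_validate",
]


# ---------------------------------------------------------------------------
# L1-penalised logistic regression (coordinate descent over a lambda path)
# ---------------------------------------------------------------------------

def _soft_threshold(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def penalized_objective(X, y, lam, beta0, beta):
    """Mean negative log-likelihood plus the L1 penalty ``lam * ||beta||_1``."""
    eta = beta0 + X @ beta
    # log(1 + exp(eta)) - y*eta, computed stably
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    return float(nll + lam * np.abs(beta).sum())


try:  # numba accelerates the inner coordinate loop ~100x; fall back cleanly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=False)
def _cd_kernel(X, y, lam, beta0, beta, max_outer, tol):  # pragma: no cover - exercised via wrapper
    n, p = X.shape
    for _outer in range(max_outer):
        eta = np.empty(n)
        for i in range(n):
            s = beta0
            for j in range(p):
                s += X[i, j] * beta[j]
            eta[i] = s
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        for i in range(n):
            if w[i] < 1e-5:
                w[i] = 1e-5
        z = eta + (y - mu) / w
        denom = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            denom[j] = s / n
        w_sum = w.sum()
        r = np.empty(n)
        for i in range(n):
            s = z[i] - beta0
            for j in range(p):
                s -= X[i, j] * beta[j]
            r[i] = s
        full_pass = True
        for _sweep in range(500):
            max_delta = 0.0
            d0 = 0.0
            for i in range(n):
                d0 += w[i] * r[i]
            d0 /= w_sum
            beta0 += d0
            for i in range(n):
                r[i] -= d0
            max_delta = abs(d0)
            for j in range(p):
                if not full_pass and beta[j] == 0.0:
                    continue
                rho = 0.0
                for i in range(n):
                    rho += w[i] * X[i, j] * r[i]
                rho = rho / n + denom[j] * beta[j]
                if rho > lam:
                    bj = (rho - lam) / denom[j]
                elif rho < -lam:
                    bj = (rho + lam) / denom[j]
                else:
                    bj = 0.0
                if bj != beta[j]:
                    diff = bj - beta[j]
                    for i in range(n):
                        r[i] -= X[i, j] * diff
                    if abs(diff) > max_delta:
                        max_delta = abs(diff)
                    beta[j] = bj
            if max_delta < tol:
                if full_pass:
                    break
                full_pass = True
            else:
                full_pass = False
        delta_eta = 0.0
        for i in range(n):
            s = beta0
            for j in range(p):
                s += X[i, j] * beta[j]
            if abs(s - eta[i]) > delta_eta:
                delta_eta = abs(s - eta[i])
        if delta_eta < 1e-9:
            break
    return beta0, beta


def _cd_logistic(X, y, lam, beta0, beta, max_outer=50, tol=1e-10, trace=None):
    """One glmnet-style fit at a fixed lambda via IRLS + coordinate descent.

    X must be standardised (columns mean 0, sd 1); the intercept is
    unpenalised.  Uses an active-set sweep strategy: full passes over
    all coordinates alternate with passes over the nonzero set until a
    full pass changes nothing.  Modifies and returns (beta0, beta).
    When ``trace`` is a list, the penalised objective is appended after
    every IRLS step (this path runs the pure-python solver).
    """
    if trace is None and _HAVE_NUMBA:
        return _cd_kernel(
            np.ascontiguousarray(X, dtype=np.float64),
            np.ascontiguousarray(y, dtype=np.float64),
            float(lam), float(beta0), beta, int(max_outer), float(tol),
        )
    n, p = X.shape
    for _ in range(max_outer):
        eta = beta0 + X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        denom = (WX * X).sum(axis=0) / n  # per-coordinate curvature
        w_sum = w.sum()
        r = z - beta0 - X @ beta
        full_pass = True
        for _ in range(500):
            coords = range(p) if full_pass else np.flatnonzero(beta)
            max_delta = 0.0
            d0 = np.dot(w, r) / w_sum
            beta0 += d0
            r -= d0
            max_delta = abs(d0)
            for j in coords:
                rho = np.dot(WX[:, j], r) / n + denom[j] * beta[j]
                bj_new = _soft_threshold(rho, lam) / denom[j]
                if bj_new != beta[j]:
                    r -= X[:, j] * (bj_new - beta[j])
                    max_delta = max(max_delta, abs(bj_new - beta[j]))
                    beta[j] = bj_new
            if max_delta < tol:
                if full_pass:
                    break
                full_pass = True
            else:
                full_pass = False
        if trace is not None:
            trace.append(penalized_objective(X, y, lam, beta0, beta))
        eta_new = beta0 + X @ beta
        if np.max(np.abs(eta_new - eta)) < 1e-9:
            break
    return beta0, beta


def lasso_path_logistic(X, y, lambdas=None, n_lambdas=50, lambda_min_ratio=None):
    """L1 logistic path with warm starts on standardised features.

    Returns ``(lambdas, beta0s, betas)`` with coefficients on the
    standardised scale (one row of ``betas`` per lambda).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if lambdas is None:
        ybar = y.mean()
        lam_max = np.max(np.abs(X.T @ (y - ybar))) / n
        if lambda_min_ratio is None:
            lambda_min_ratio = 1e-4 if n > p else 1e-2
        lambdas = lam_max * np.logspace(0, np.log10(lambda_min_ratio), n_lambdas)
    lambdas = np.asarray(lambdas, dtype=float)
    beta0 = float(np.log(y.mean() / (1 - y.mean()))) if 0 < y.mean() < 1 else 0.0
    beta = np.zeros(p)
    beta0s, betas = [], []
    for lam in lambdas:
        beta0, beta = _cd_logistic(X, y, lam, beta0, beta.copy())
        beta0s.append(beta0)
        betas.append(beta.copy())
    return lambdas, np.array(beta0s), np.array(betas)


def _binomial_deviance(y, eta):
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))


def _stratified_fold_ids(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    ids = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            ids[chunk] = f
    return ids


def lasso_select(
    x: pd.DataFrame,
    samples: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
) -> list[tuple[str, float]]:
    """Select candidate features by cross-validated L1 logistic regression.

    ``x`` is features x samples restricted to the candidate genes.
    Features are standardised internally; the lambda grid is shared
    across folds; the penalty is chosen as the CV-deviance minimiser
    (``lambda_rule="min"``, default) or the largest lambda within one
    standard error of it (``"1se"``).  Returns ``(feature, coefficient)``
    pairs with nonzero coefficients at the chosen lambda, coefficients
    reported on the original (unstandardised) scale.
    """
    if x.shape[0] < 2:
        raise ValueError("need at least 2 candidate features")
    if n_folds < 2:
        raise ValueError("need at least 2 cross-validation folds")
    if lambda_rule not in {"min", "1se"}:
        raise ValueError("lambda_rule must be 'min' or '1se'")
    t = samples.set_index("sample_id")
    y = np.array([1.0 if t.loc[s, "group"] == "case" else 0.0 for s in x.columns])
    X = x.to_numpy(dtype=float).T  # samples x features
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    lambdas, _, _ = lasso_path_logistic(Xs, y)
    rng = np.random.default_rng(seed)
    folds = _stratified_fold_ids(y, n_folds, rng)
    dev = np.zeros((n_folds, lambdas.size))
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        _, b0s, bs = lasso_path_logistic(Xs[tr], y[tr], lambdas=lambdas)
        for i in range(lambdas.size):
            eta = b0s[i] + Xs[te] @ bs[i]
            dev[f, i] = _binomial_deviance(y[te], eta)
    mean_dev = dev.mean(axis=0)
    i_min = int(np.argmin(mean_dev))
    if lambda_rule == "1se":
        se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        ok = np.flatnonzero(mean_dev <= mean_dev[i_min] + se[i_min])
        i_sel = int(ok[0])  # lambdas are descending: first = largest feasible
    else:
        i_sel = i_min
    _, b0s, bs = lasso_path_logistic(Xs, y, lambdas=lambdas)
    coefs = bs[i_sel] / sd  # back to original scale
    selected = [
        (str(g), float(c))
        for g, c, raw in zip(x.index, coefs, bs[i_sel])
        if raw != 0
    ]
    if not selected:
        warnings.warn("LASSO selected no features at the chosen lambda", stacklevel=2)
    return selected


# ---------------------------------------------------------------------------
# Random forest (bagged regression trees on the 0/1 response)
# ---------------------------------------------------------------------------

@dataclass
class SignatureModel:
    """Frozen diagnostic signature: selected genes + fitted forest."""

    features: list[str]
    lasso_coefficients: dict[str, float]
    trees: list = field(default_factory=list, repr=False)
    n_trees: int = 1000
    seed: int = 0
    importance: pd.DataFrame | None = None  # %IncMSE, IncNodePurity per feature


def _node_purity_decrease(tree, n_features: int) -> np.ndarray:
    """Total impurity decrease attributed to each split feature of a tree."""
    t = tree.tree_
    imp = np.zeros(n_features)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        n = t.weighted_n_node_samples
        decrease = (
            n[node] * t.impurity[node]
            - n[left] * t.impurity[left]
            - n[right] * t.impurity[right]
        )
        imp[t.feature[node]] += decrease
    return imp


def rf_fit_and_importance(
    x: pd.DataFrame,
    samples: pd.DataFrame,
    n_trees: int = 1000,
    seed: int = 0,
    compute_importance: bool = True,
) -> SignatureModel:
    """Bagged regression trees on the 0/1 response with OOB importances.

    Each tree sees a bootstrap resample and sqrt(p) candidate features
    per split.  %IncMSE is the mean percentage increase in a tree's
    out-of-bag squared error after permuting one feature; IncNodePurity
    is the total impurity decrease credited to the feature, summed over
    trees.
    """
    if x.shape[0] == 0:
        raise ValueError("no selected features to fit")
    t = samples.set_index("sample_id")
    y = np.array([1.0 if t.loc[s, "group"] == "case" else 0.0 for s in x.columns])
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    X = x.to_numpy(dtype=float).T
    n, p = X.shape
    rng = np.random.default_rng(seed)
    trees = []
    inc_mse = np.zeros((n_trees, p))
    inc_mse_valid = np.zeros((n_trees, p), dtype=bool)
    purity = np.zeros(p)
    for b in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        # min_samples_leaf=5 mirrors the classic regression-forest default
        # (nodesize 5); fully grown trees inflate null permutation importance
        tree = DecisionTreeRegressor(
            max_features="sqrt", min_samples_leaf=5,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        purity += _node_purity_decrease(tree, p)
        if not compute_importance or oob.size == 0:
            continue
        base_mse = np.mean((tree.predict(X[oob]) - y[oob]) ** 2)
        for j in range(p):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            perm_mse = np.mean((tree.predict(Xp) - y[oob]) ** 2)
            if base_mse > 0:
                inc_mse[b, j] = 100.0 * (perm_mse - base_mse) / base_mse
            else:
                inc_mse[b, j] = 100.0 * (perm_mse - base_mse)
            inc_mse_valid[b, j] = True
    with np.errstate(invalid="ignore"):
        pct_inc = np.where(
            inc_mse_valid.sum(axis=0) > 0,
            inc_mse.sum(axis=0) / np.maximum(inc_mse_valid.sum(axis=0), 1),
            0.0,
        )
    importance = pd.DataFrame(
        {"%IncMSE": pct_inc, "IncNodePurity": purity}, index=x.index
    )
    return SignatureModel(
        features=list(map(str, x.index)),
        lasso_coefficients={},
        trees=trees,
        n_trees=n_trees,
        seed=seed,
        importance=importance,
    )


def predict_scores(model: SignatureModel, x: pd.DataFrame) -> pd.Series:
    """Forest-averaged score per sample (x is features x samples).

    Features absent from ``x`` raise, listing them — required for
    external-cohort validation where the platform may lack genes.
    """
    missing = [f for f in model.features if f not in x.index]
    if missing:
        raise ValueError(f"features absent from expression matrix: {missing}")
    X = x.loc[model.features].to_numpy(dtype=float).T
    preds = np.mean([t.predict(X) for t in model.trees], axis=0)
    return pd.Series(preds, index=x.columns, name="score")


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """ROC curve points and the rank-based AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def auc_score(scores, labels) -> float:
    """AUC by the Mann-Whitney rank formulation, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1 if labels.dtype != object else labels == "case"
    n1, n2 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes required to compute AUC")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def roc_curve_points(scores, labels):
    """Sensitivity/specificity at every distinct score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1 if labels.dtype != object else labels == "case"
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    sens, spec = [], []
    p, n = pos.sum(), (~pos).sum()
    for thr in thresholds:
        called = scores >= thr
        sens.append((called & pos).sum() / p)
        spec.append((~called & ~pos).sum() / n)
    return thresholds, np.array(sens), np.array(spec)


def evaluate_roc(model: SignatureModel, x: pd.DataFrame, samples: pd.DataFrame) -> RocResult:
    """Score a cohort with a frozen model and report its ROC/AUC."""
    t = samples.set_index("sample_id")
    labels = np.array([1 if t.loc[s, "group"] == "case" else 0 for s in x.columns])
    if np.unique(labels).size < 2:
        raise ValueError("both classes required for ROC")
    scores = predict_scores(model, x).to_numpy()
    thr, sens, spec = roc_curve_points(scores, labels)
    return RocResult(thr, sens, spec, auc_score(scores, labels))


# ---------------------------------------------------------------------------
# Splitting and cross-validation
# ---------------------------------------------------------------------------

def split_train_validation(
    samples: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/validation split of the sample table."""
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    train_idx, valid_idx = [], []
    for grp in ("control", "case"):
        idx = samples.index[samples["group"] == grp].to_numpy()
        if idx.size < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")
        perm = idx[rng.permutation(idx.size)]
        n_train = int(round(train_fraction * idx.size))
        train_idx.extend(perm[:n_train])
        valid_idx.extend(perm[n_train:])
    if not valid_idx:
        warnings.warn("validation split is empty (train_fraction = 1)", stacklevel=2)
    train = samples.loc[sorted(train_idx)].reset_index(drop=True)
    valid = samples.loc[sorted(valid_idx)].reset_index(drop=True)
    return train, valid


def cross_validate(
    x: pd.DataFrame,
    samples: pd.DataFrame,
    n_folds: int = 5,
    seed: int = 0,
    n_trees: int = 200,
    lasso_folds: int = 10,
) -> tuple[float, list[float]]:
    """Stratified k-fold CV of the whole LASSO -> forest pipeline.

    Selection and fitting are redone inside every fold; if LASSO keeps
    nothing in a fold, all candidates are used for that fold's forest.
    Returns (mean AUC, per-fold AUCs).
    """
    t = samples.set_index("sample_id")
    y = np.array([1.0 if t.loc[s, "group"] == "case" else 0.0 for s in x.columns])
    rng = np.random.default_rng(seed)
    folds = _stratified_fold_ids(y, n_folds, rng)
    aucs = []
    cols = np.array(x.columns)
    for f in range(n_folds):
        te = folds == f
        if np.unique(y[te]).size < 2 or np.unique(y[~te]).size < 2:
            raise ValueError(
                f"fold {f} lost a class; use fewer folds for this sample size"
            )
        tr_cols, te_cols = cols[~te].tolist(), cols[te].tolist()
        tr_samples = samples[samples["sample_id"].isin(tr_cols)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = lasso_select(
                x[tr_cols], tr_samples,
                n_folds=max(
                    2,
                    min(lasso_folds, int(min((y[~te] == 1).sum(), (y[~te] == 0).sum()))),
                ),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        feats = [g for g, _ in sel] or list(map(str, x.index))
        model = rf_fit_and_importance(
            x.loc[feats, tr_cols], tr_samples,
            n_trees=n_trees, seed=int(rng.integers(0, 2**31 - 1)),
            compute_importance=False,
        )
        scores = predict_scores(model, x.loc[feats, te_cols]).to_numpy()
        aucs.append(auc_score(scores, y[te]))
    return float(np.mean(aucs)), aucs
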