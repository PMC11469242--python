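"""Cohort statistics for FAZ biomarkers vs. CAD severity.

Four stages:

* group-difference testing with a normality/homoscedasticity gate
  (Shapiro–Wilk + Levene): ANOVA + Tukey HSD when the parametric
  assumptions hold, otherwise Kruskal–Wallis + Dunn's test with Holm
  correction; an optional Bonferroni factor accounts for testing several
  metrics;
* zero-inflated Poisson (ZIP) regression of the Gensini score on one
  metric with age/sex/diabetes adjustment, in both the count and the
  structural-zero (inflation) part;
* predictive modelling: binary logistic or ordinal logistic regression in
  stratified fivefold cross-validation, with SMOTE oversampling applied to
  the training folds only;
* intergrader agreement: Dice / Jaccard on rasterized segmentations and
  Bland–Altman bias with 95% limits of agreement on paired metric values.

SMOTE (interpolation between a minority sample and one of its k nearest
minority neighbours) and Dunn's rank test are implemented here directly;
both are small, standard procedures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .errors import DataError, ParameterError

ORDINAL_VARIANTS = ("cumulative", "immediate_threshold")


# ---------------------------------------------------------------------------
# group-difference tests

def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def dunn_test(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's pairwise z tests on the pooled Kruskal–Wallis ranks, with tie
    correction and Holm adjustment."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    n = len(values)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: (groups == g).sum() for g in labels}
    rows = []
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": g1, "group_b": g2, "z": z, "p_unadj": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = _holm(out["p_unadj"].to_numpy())
    return out


def group_difference_tests(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "ternary_group",
    gate_alpha: float = 0.05,
    bonferroni_factor: int = 1,
) -> pd.DataFrame:
    """Pairwise adjusted p-values for one metric across severity groups.

    The pathway is chosen by the stated gates: if every group passes
    Shapiro–Wilk normality and Levene's test finds homogeneous variances,
    one-way ANOVA with Tukey HSD is used; otherwise Kruskal–Wallis with
    Dunn/Holm.  ``bonferroni_factor`` multiplies the adjusted p-values when
    several metrics are tested in the same family.
    """
    sub = table[[metric, group_col]].dropna()
    labels = np.unique(sub[group_col])
    samples = [sub.loc[sub[group_col] == g, metric].to_numpy() for g in labels]
    if len(samples) < 2 or any(len(s) < 3 for s in samples):
        raise DataError("need >= 2 groups with >= 3 observations each")

    normal = all(sps.shapiro(s).pvalue > gate_alpha for s in samples)
    homoscedastic = sps.levene(*samples).pvalue > gate_alpha

    if normal and homoscedastic:
        pathway = "anova_tukey"
        omnibus_p = sps.f_oneway(*samples).pvalue
        tk = sps.tukey_hsd(*samples)
        rows = [
            {"group_a": labels[i], "group_b": labels[j],
             "p_adj": float(tk.pvalue[i, j])}
            for i, j in combinations(range(len(labels)), 2)
        ]
        pairs = pd.DataFrame(rows)
    else:
        pathway = "kruskal_dunn_holm"
        omnibus_p = sps.kruskal(*samples).pvalue
        pairs = dunn_test(sub[metric].to_numpy(), sub[group_col].to_numpy())
        pairs = pairs[["group_a", "group_b", "p_adj"]].copy()

    if bonferroni_factor < 1:
        raise ParameterError("bonferroni_factor must be >= 1")
    pairs["p_adj_bonferroni"] = np.minimum(1.0, pairs["p_adj"] * bonferroni_factor)
    pairs.insert(0, "metric", metric)
    pairs["pathway"] = pathway
    pairs["omnibus_p"] = omnibus_p
    return pairs


# ---------------------------------------------------------------------------
# zero-inflated Poisson effect model

def fit_zip(table: pd.DataFrame, metric: str, eye: Optional[str] = None,
            maxiter: int = 500) -> pd.DataFrame:
    """ZIP regression of the (rounded) Gensini score on one standardized
    metric plus age, sex and diabetes, in both the Poisson-count and the
    structural-zero part.  Returns a coefficient table with columns
    ``part`` (count/inflate), ``term``, ``coef``, ``se``, ``p``.
    """
    import statsmodels.api as sm
    from statsmodels.discrete.count_model import ZeroInflatedPoisson

    sub = table if eye is None else table[table["eye"] == eye]
    cols = [metric, "age_y", "sex", "diabetes", "gs"]
    sub = sub[cols].dropna()
    if len(sub) < 30:
        raise DataError("ZIP fit needs >= 30 rows")
    endog = np.round(sub["gs"].to_numpy()).astype(int)
    X = sub[[metric, "age_y", "sex", "diabetes"]].astype(float).copy()
    # standardize continuous predictors for numerical stability
    for c in (metric, "age_y"):
        sd = X[c].std()
        if sd > 0:
            X[c] = (X[c] - X[c].mean()) / sd
    exog = sm.add_constant(X, has_constant="add")

    if (endog == 0).sum() == 0:
        import warnings

        warnings.warn("outcome has no zeros: zero-inflation is degenerate, "
                      "falling back to a plain Poisson model")
        res = sm.GLM(endog, exog, family=sm.families.Poisson()).fit()
        return pd.DataFrame({
            "part": "count", "term": exog.columns,
            "coef": res.params.to_numpy(), "se": res.bse.to_numpy(),
            "p": res.pvalues.to_numpy(),
        })

    model = ZeroInflatedPoisson(endog, exog, exog_infl=exog, inflation="logit")
    res = model.fit(method="bfgs", maxiter=maxiter, disp=0)
    names = list(res.params.index)
    parts = ["inflate" if n.startswith("inflate_") else "count" for n in names]
    terms = [n.replace("inflate_", "") for n in names]
    return pd.DataFrame({
        "part": parts, "term": terms,
        "coef": res.params.to_numpy(), "se": res.bse.to_numpy(),
        "p": res.pvalues.to_numpy(),
    })


# ---------------------------------------------------------------------------
# SMOTE + cross-validated prediction

def smote(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
          rng: np.random.Generator | None = None):
    """Oversample every minority class to the majority size by interpolating
    between a random minority sample and one of its k nearest same-class
    neighbours.  Returns ``(X_out, y_out, n_original)`` with all synthetic
    rows appended after the originals.
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, float)
    y = np.asarray(y)
    n_original = len(y)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    synth_X, synth_y = [], []
    for cls, cnt in zip(classes, counts):
        need = n_max - cnt
        if need == 0:
            continue
        Xc = X[y == cls]
        if len(Xc) < 2:
            raise DataError(f"class {cls!r} has < 2 samples; cannot SMOTE")
        k = min(k_neighbors, len(Xc) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)
        base = rng.integers(0, len(Xc), need)
        pick = idx[base, rng.integers(1, k + 1, need)]
        gamma = rng.uniform(0.0, 1.0, need)[:, None]
        synth_X.append(Xc[base] + gamma * (Xc[pick] - Xc[base]))
        synth_y.append(np.full(need, cls, dtype=y.dtype))
    if synth_X:
        X = np.vstack([X] + synth_X)
        y = np.concatenate([y] + synth_y)
    return X, y, n_original


@dataclass(frozen=True)
class CvResult:
    task: str
    metric: Optional[str]
    fold_aucs: tuple
    mean_auc: float
    auc_ci95: tuple
    f1: float
    accuracy: float
    precision: float
    recall: float
    fold_details: tuple = field(default_factory=tuple, repr=False)


def _immediate_threshold_fit_predict(X_tr, y_tr, X_te, classes, rng):
    """Immediate-threshold ordinal model as a chain of conditional binary
    logits: P(Y = j | Y >= j) is logistic at each threshold, and class
    probabilities telescope through the chain."""
    probs = np.ones((len(X_te), len(classes)))
    surv = np.ones(len(X_te))
    for j, cls in enumerate(classes[:-1]):
        at_risk = y_tr >= cls
        Xr, yr = X_tr[at_risk], (y_tr[at_risk] == cls).astype(int)
        if yr.min() == yr.max():  # all one class at this threshold
            p_stop = np.full(len(X_te), float(yr.mean()))
        else:
            clf = LogisticRegression(max_iter=2000)
            clf.fit(Xr, yr)
            p_stop = clf.predict_proba(X_te)[:, 1]
        probs[:, j] = surv * p_stop
        surv = surv * (1.0 - p_stop)
    probs[:, -1] = surv
    return probs / probs.sum(axis=1, keepdims=True)


def _ordinal_fit_predict(X_tr, y_tr, X_te, classes, variant, rng):
    if variant == "immediate_threshold":
        return _immediate_threshold_fit_predict(X_tr, y_tr, X_te, classes, rng)
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    endog = pd.Series(pd.Categorical(y_tr, categories=list(classes), ordered=True))
    model = OrderedModel(endog, X_tr, distr="logit")
    res = model.fit(method="bfgs", maxiter=500, disp=0)
    return np.asarray(res.model.predict(res.params, exog=X_te))


def predict_cv(
    table: pd.DataFrame,
    metric: Optional[str],
    task: str = "binary",
    seed: int = 0,
    n_folds: int = 5,
    smote_k: int = 5,
    ordinal_variant: str = "cumulative",
    group_col: Optional[str] = None,
) -> CvResult:
    """Stratified fivefold CV of a severity classifier on one FAZ metric.

    Predictors are age and sex (the baseline model) plus ``metric`` when
    given.  ``task='binary'`` uses the binary severity groups (rows in the
    excluded GS band are dropped) and logistic regression with ROC AUC;
    ``task='ternary'`` uses the three severity groups and an ordinal
    logistic model with macro one-vs-rest AUC.  SMOTE balances the training
    folds only; test folds contain exclusively original rows (asserted via
    ``fold_details``).
    """
    if task not in ("binary", "ternary"):
        raise ParameterError("task must be 'binary' or 'ternary'")
    if ordinal_variant not in ORDINAL_VARIANTS:
        raise ParameterError(f"ordinal_variant must be one of {ORDINAL_VARIANTS}")
    group_col = group_col or ("binary_group" if task == "binary" else "ternary_group")
    feats = ["age_y", "sex"] + ([metric] if metric else [])
    sub = table.dropna(subset=feats + [group_col])
    if task == "binary":
        sub = sub[sub[group_col].isin([0, 1])]
    y = sub[group_col].astype(int).to_numpy()
    X = sub[feats].astype(float).to_numpy()
    classes = np.unique(y)
    counts = {c: int((y == c).sum()) for c in classes}
    if len(classes) < 2 or min(counts.values()) < 5:
        raise DataError(f"every class needs >= 5 rows, got {counts}")

    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    # standardize once for optimizer stability (fold-wise stats differ little)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    fold_aucs, details = [], []
    y_true_all, y_pred_all = [], []
    for fold, (tr, te) in enumerate(skf.split(Xs, y)):
        X_res, y_res, n_orig = smote(Xs[tr], y[tr], k_neighbors=smote_k, rng=rng)
        if task == "binary":
            clf = LogisticRegression(max_iter=2000)
            clf.fit(X_res, y_res)
            p = clf.predict_proba(Xs[te])[:, 1]
            fold_aucs.append(roc_auc_score(y[te], p))
            pred = (p >= 0.5).astype(int)
        else:
            probs = _ordinal_fit_predict(X_res, y_res, Xs[te], classes,
                                         ordinal_variant, rng)
            fold_aucs.append(roc_auc_score(y[te], probs, multi_class="ovr",
                                           average="macro"))
            pred = classes[np.argmax(probs, axis=1)]
        y_true_all.append(y[te])
        y_pred_all.append(pred)
        details.append({
            "fold": fold,
            "test_indices": tuple(sub.index[te]),
            "n_train_original": int(len(tr)),
            "n_train_synthetic": int(len(y_res) - len(tr)),
            "n_test": int(len(te)),
        })

    aucs = np.asarray(fold_aucs)
    # t-interval over the fold AUCs
    half = sps.t.ppf(0.975, len(aucs) - 1) * aucs.std(ddof=1) / np.sqrt(len(aucs))
    yt = np.concatenate(y_true_all)
    yp = np.concatenate(y_pred_all)
    avg = "binary" if task == "binary" else "macro"
    return CvResult(
        task=task, metric=metric,
        fold_aucs=tuple(float(a) for a in aucs),
        mean_auc=float(aucs.mean()),
        auc_ci95=(float(aucs.mean() - half), float(aucs.mean() + half)),
        f1=float(f1_score(yt, yp, average=avg)),
        accuracy=float(accuracy_score(yt, yp)),
        precision=float(precision_score(yt, yp, average=avg, zero_division=0)),
        recall=float(recall_score(yt, yp, average=avg, zero_division=0)),
        fold_details=tuple(details),
    )


# ---------------------------------------------------------------------------
# intergrader agreement

def dice_jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """Overlap of two binary masks on the same image frame."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise DataError("grader masks must share the same image frame")
    inter = float(np.logical_and(a, b).sum())
    sa, sb = float(a.sum()), float(b.sum())
    union = sa + sb - inter
    if sa + sb == 0:
        return 1.0, 1.0  # both empty: perfect (vacuous) agreement
    dice = 2.0 * inter / (sa + sb)
    jaccard = inter / union if union > 0 else 1.0
    return dice, jaccard


def bland_altman(values_a, values_b) -> dict:
    """Bias and 95% limits of agreement of paired measurements."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise DataError("need two equal-length 1D arrays with >= 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    spread = 1.96 * float(diff.std(ddof=1))
    return {"bias": bias, "loa_low": bias - spread, "loa_high": bias + spread}


def intergrader(mask_a: np.ndarray, mask_b: np.ndarray,
                metrics_a=None, metrics_b=None) -> dict:
    """Agreement between two graders of the same eye: Dice/Jaccard on the
    masks and, when paired metric values are supplied, Bland–Altman."""
    dice, jaccard = dice_jaccard(mask_a, mask_b)
    out = {"dice": dice, "jaccard": jaccard}
    if metrics_a is not None and metrics_b is not None:
        out["bland_altman"] = bland_altman(metrics_a, metrics_b)
    return out
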