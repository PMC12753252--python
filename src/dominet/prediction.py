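"""Leave-one-site-out prediction from regional centrality features.

Each acquisition site serves once as the held-out test set; features are
standardized on the training sites only (no leakage), a linear support-vector
machine with Platt-calibrated pseudoprobabilities classifies diagnosis, and a
linear support-vector regressor predicts cognition.  Region-wise
centrality-cognition association maps adjust for age, sex and site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .mega import fdr_bh, linear_model_t

__all__ = [
    "LosoSplit",
    "ClassificationReport",
    "loso_splits",
    "loso_classify",
    "loso_regress_scores",
    "cognition_association",
]


@dataclass
class LosoSplit:
    test_site: str
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class ClassificationReport:
    per_site: pd.DataFrame  # site, acc, sen, spe, auc, n_test
    mean_metrics: dict[str, float]
    pseudoprob: np.ndarray  # per-subject P(positive class), NaN if never tested
    labels: np.ndarray


def loso_splits(sites: np.ndarray) -> list[LosoSplit]:
    """One split per site: that site's subjects test, all others train."""
    sites = np.asarray(sites)
    splits = []
    for site_id in sorted(pd.unique(sites)):
        test = np.flatnonzero(sites == site_id)
        train = np.flatnonzero(sites != site_id)
        splits.append(LosoSplit(test_site=str(site_id), train_idx=train, test_idx=test))
    if len(splits) < 2:
        raise ValueError("leave-one-site-out needs at least 2 sites")
    return splits


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    acc = (tp + tn) / max(tp + tn + fp + fn, 1)
    sen = tp / (tp + fn) if tp + fn else np.nan
    spe = tn / (tn + fp) if tn + fp else np.nan
    return acc, sen, spe


def loso_classify(
    features: np.ndarray,
    labels: np.ndarray,
    sites: np.ndarray,
    positive_label: str = "AD",
    C: float = 1.0,
    seed: int = 0,
) -> ClassificationReport:
    """Leave-one-site-out linear-SVM classification with pseudoprobabilities.

    Per fold, features are z-scored with training-fold statistics only, a
    linear SVC (Platt probability calibration, seeded) is fitted, and ACC /
    SEN / SPE / AUC are evaluated on the held-out site.  SEN is the recall of
    ``positive_label``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    y = (labels == positive_label).astype(int)
    rows = []
    prob = np.full(len(y), np.nan)
    for split in loso_splits(sites):
        y_tr = y[split.train_idx]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(
                f"training fold for held-out site {split.test_site!r} has a single class"
            )
        scaler = StandardScaler().fit(features[split.train_idx])
        clf = SVC(kernel="linear", C=C, probability=True, random_state=seed)
        clf.fit(scaler.transform(features[split.train_idx]), y_tr)
        Xte = scaler.transform(features[split.test_idx])
        y_te = y[split.test_idx]
        p_pos = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)]
        y_hat = clf.predict(Xte)
        prob[split.test_idx] = p_pos
        acc, sen, spe = _confusion_metrics(y_te, y_hat)
        auc = roc_auc_score(y_te, p_pos) if len(np.unique(y_te)) == 2 else np.nan
        rows.append(
            {"site": split.test_site, "acc": acc, "sen": sen, "spe": spe,
             "auc": auc, "n_test": len(y_te)}
        )
    per_site = pd.DataFrame(rows)
    mean_metrics = {
        m: float(np.nanmean(per_site[m])) for m in ("acc", "sen", "spe", "auc")
    }
    return ClassificationReport(
        per_site=per_site, mean_metrics=mean_metrics, pseudoprob=prob, labels=labels
    )


def loso_regress_scores(
    features: np.ndarray,
    scores: np.ndarray,
    sites: np.ndarray,
    C: float = 1.0,
    average: str = "per_site",
) -> dict:
    """Leave-one-site-out cognition prediction (linear support-vector regression).

    Returns pooled predictions plus Pearson r, RMSE and R^2 against the
    actual scores.  ``average="per_site"`` (default) reports r as the mean of
    per-site correlations; ``"pooled"`` correlates all held-out predictions
    at once.  Test folds with constant actual scores contribute no
    correlation (reported as missing).
    """
    features = np.asarray(features, dtype=float)
    scores = np.asarray(scores, dtype=float)
    pred = np.full(len(scores), np.nan)
    per_site_r = []
    for split in loso_splits(sites):
        scaler = StandardScaler().fit(features[split.train_idx])
        reg = SVR(kernel="linear", C=C)
        reg.fit(scaler.transform(features[split.train_idx]), scores[split.train_idx])
        yhat = reg.predict(scaler.transform(features[split.test_idx]))
        pred[split.test_idx] = yhat
        actual = scores[split.test_idx]
        if np.std(actual) > 0 and np.std(yhat) > 0:
            per_site_r.append(float(stats.pearsonr(yhat, actual)[0]))
        else:
            per_site_r.append(np.nan)
    rmse = float(np.sqrt(np.mean((pred - scores) ** 2)))
    ss_res = float(np.sum((scores - pred) ** 2))
    ss_tot = float(np.sum((scores - scores.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    pooled_r = (
        float(stats.pearsonr(pred, scores)[0]) if np.std(pred) > 0 else np.nan
    )
    r = float(np.nanmean(per_site_r)) if average == "per_site" else pooled_r
    return {
        "predicted": pred,
        "r": r,
        "pooled_r": pooled_r,
        "per_site_r": per_site_r,
        "rmse": rmse,
        "r2": r2,
    }


def cognition_association(
    centrality: np.ndarray,
    score: np.ndarray,
    covariates: pd.DataFrame,
    sites: np.ndarray,
    q: float = 0.05,
) -> pd.DataFrame:
    """Region-wise centrality ~ cognition association, adjusted for covariates.

    Per region fits centrality ~ score + age + sex + site (sites as indicator
    columns, first site the reference) and reports the T of the cognition
    coefficient with BH-FDR flags across regions.
    """
    centrality = np.asarray(centrality, dtype=float)
    score = np.asarray(score, dtype=float)
    sites = np.asarray(sites)
    cols = [np.ones(len(score)), score]
    names = ["intercept", "score"]
    for cname in covariates.columns:
        cols.append(np.asarray(covariates[cname], dtype=float))
        names.append(str(cname))
    site_levels = sorted(pd.unique(sites))
    for lvl in site_levels[1:]:
        cols.append((sites == lvl).astype(float))
        names.append(f"site[{lvl}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates or sites)")
    t, p = linear_model_t(centrality, X, coef_index=1, names=names)
    p_adj, reject = fdr_bh(p, q=q)
    return pd.DataFrame(
        {
            "region": np.arange(1, centrality.shape[1] + 1),
            "t": t,
            "p": p,
            "p_adjusted": p_adj,
            "significant": reject,
        }
    )
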