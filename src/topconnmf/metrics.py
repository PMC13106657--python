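"""Reconstruction and selection-quality metrics.

Matrix-agreement metrics (RE, RMSD, SSIM, NMI, CC) compare the data
matrix with its reconstruction ``W H``; selection quality is measured by
repeated cross-validated classification (decision tree, the CART-style
learner) restricted to a selected feature subset, summarized as AUC and
AUPR over repeats; and Welch's t-test with Cohen's d compares two run
summaries given only their means and standard deviations.

Conventions for the matrix metrics (stated here because they matter and
are otherwise underdetermined):

* SSIM is computed *globally* — one window covering the whole matrix —
  with the standard stabilizing constants ``C1 = (0.01 L)^2``,
  ``C2 = (0.03 L)^2`` after jointly rescaling both matrices to [0, 1]
  by their common maximum (so ``L = 1``).  A negative global index
  (anticorrelated structure) is floored at 0: for nonnegative
  expression reconstructions the meaningful similarity range is [0, 1].
* NMI discretizes both flattened matrices into 16 equal-width bins over
  their joint range and applies the standard normalized mutual
  information of the two labelings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    normalized_mutual_info_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateClassError, DimensionError, ValidationError
from .expression import ExpressionMatrix, as_values


@dataclass
class RunSummary:
    """Per-run metric values with their mean and standard deviation."""

    name: str
    values: np.ndarray
    mean: float
    sd: float

    @classmethod
    def from_values(cls, name: str, values) -> "RunSummary":
        values = np.asarray(values, dtype=float)
        return cls(
            name=name,
            values=values,
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        )

    @property
    def n_runs(self) -> int:
        return int(self.values.size)


def _global_ssim(x: np.ndarray, y: np.ndarray) -> float:
    c1 = 0.01**2
    c2 = 0.03**2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    val = ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )
    return float(max(val, 0.0))


def matrix_metrics(X, Xhat, n_bins: int = 16) -> dict[str, float]:
    """Agreement metrics between a matrix and its reconstruction.

    Returns ``re`` (Frobenius norm of the difference), ``rmsd``
    (``re / sqrt(g s)``), ``ssim``, ``nmi`` and ``cc`` under the module
    conventions.  Identical inputs give re = rmsd = 0 and
    ssim = nmi = cc = 1.
    """
    Xv = as_values(X)
    Xh = as_values(Xhat)
    if Xv.shape != Xh.shape:
        raise DimensionError(f"shape mismatch: {Xv.shape} vs {Xh.shape}")
    diff = Xv - Xh
    re = float(np.linalg.norm(diff, "fro"))
    rmsd = re / np.sqrt(Xv.size)

    identical = np.array_equal(Xv, Xh)

    scale = max(Xv.max(), Xh.max())
    if scale <= 0:
        ssim = 1.0 if identical else 0.0
    else:
        ssim = _global_ssim(Xv / scale, Xh / scale)

    xf, yf = Xv.ravel(), Xh.ravel()
    if identical:
        cc = 1.0
        nmi = 1.0
    else:
        if xf.std() == 0 or yf.std() == 0:
            cc = 0.0
        else:
            cc = float(np.corrcoef(xf, yf)[0, 1])
        lo = min(xf.min(), yf.min())
        hi = max(xf.max(), yf.max())
        edges = np.linspace(lo, hi, n_bins + 1)
        lx = np.clip(np.digitize(xf, edges[1:-1]), 0, n_bins - 1)
        ly = np.clip(np.digitize(yf, edges[1:-1]), 0, n_bins - 1)
        nmi = float(normalized_mutual_info_score(lx, ly))
    return {"re": re, "rmsd": float(rmsd), "ssim": ssim, "nmi": nmi, "cc": cc}


def welch_summary_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> dict[str, float]:
    """Welch's t-test and Cohen's d from summary statistics.

    ``t`` uses the Welch standard error, the two-sided ``p`` uses the
    Welch-Satterthwaite degrees of freedom, and ``cohens_d`` divides the
    mean difference by the pooled standard deviation.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        raise ValidationError("both variances are zero; Welch's t is undefined")
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = (mean1 - mean2) / pooled
    return {"t": float(t), "p": float(p), "cohens_d": float(d)}


def selection_auc(
    X,
    labels,
    selected_features,
    n_repeats: int = 30,
    seed: int = 0,
    n_splits: int = 5,
) -> dict[str, RunSummary]:
    """Repeated cross-validated classification on a feature subset.

    Runs ``n_repeats`` stratified ``n_splits``-fold cross-validations of
    a decision-tree classifier restricted to ``selected_features``
    (column indices, or feature ids when ``X`` is an
    :class:`ExpressionMatrix`), scoring AUC and AUPR per repeat.
    Deterministic given ``seed``.
    """
    if isinstance(X, ExpressionMatrix):
        ids = {f: j for j, f in enumerate(X.feature_ids)}
        cols = [ids[f] if isinstance(f, str) else int(f) for f in selected_features]
        Xv = X.values[:, cols]
    else:
        Xv = np.asarray(X, dtype=float)[:, np.asarray(selected_features, dtype=int)]
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if classes.size < 2:
        raise DegenerateClassError("need at least two classes for classification")
    if classes.size > 2:
        raise ValidationError("binary labels expected")
    y = (y_raw == classes[1]).astype(int)  # positive class: lexicographically later
    aucs = np.zeros(n_repeats)
    auprs = np.zeros(n_repeats)
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + r)
        fold_auc, fold_aupr = [], []
        for train, test in skf.split(Xv, y):
            clf = DecisionTreeClassifier(random_state=seed + r)
            clf.fit(Xv[train], y[train])
            proba = clf.predict_proba(Xv[test])
            score = proba[:, 1] if proba.shape[1] == 2 else np.zeros(len(test))
            if np.unique(y[test]).size < 2:
                continue  # fold without both classes carries no ranking signal
            fold_auc.append(roc_auc_score(y[test], score))
            fold_aupr.append(average_precision_score(y[test], score))
        aucs[r] = float(np.mean(fold_auc))
        auprs[r] = float(np.mean(fold_aupr))
    return {
        "auc": RunSummary.from_values("auc", aucs),
        "aupr": RunSummary.from_values("aupr", auprs),
    }
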