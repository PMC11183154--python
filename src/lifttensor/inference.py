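"""Factor-based statistics on the participant and trial modes.

Given a fitted decomposition, the participant-factor columns (one
recruitment level per participant and component) feed four analyses:

* age-group classification with a linear SVM under leave-one-out
  cross-validation, over all non-empty subsets of components, scored by
  pooled-decision-value AUC and accuracy;
* permutation importance: one column is shuffled across participants many
  times and the unpermuted performance is located within the null
  distribution;
* ordinary least-squares regression of age or dexterity on the factor
  columns, with per-coefficient t-test p-values;
* Pearson correlations (with optional outlier exclusion) under Bonferroni
  correction.

The trial-factor columns are tested for monotone trends with the
Mann-Kendall test (tie-corrected variance, continuity-corrected z) and
summarized by an OLS slope over the trial index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

__all__ = [
    "ClassificationResult",
    "PermutationResult",
    "RegressionResult",
    "CorrelationResult",
    "TrendResult",
    "loocv_svm",
    "subset_search",
    "permutation_importance",
    "fit_regression",
    "correlate",
    "mann_kendall",
    "group_difference_test",
]

#: Class encoding: larger decision values mean "older adult".
POSITIVE_CLASS = "OA"


@dataclass
class ClassificationResult:
    """Leave-one-out SVM performance for one subset of factor columns."""

    factor_subset: tuple[int, ...]
    auc: float
    acc: float
    predicted: np.ndarray = field(repr=False)       # predicted labels (0/1)
    decision_values: np.ndarray = field(repr=False)  # held-out decision values


@dataclass
class PermutationResult:
    """Null distribution of performance with one factor column permuted."""

    factor_index: int
    n_perm: int
    null_auc: np.ndarray
    null_acc: np.ndarray
    percentile_auc: float
    percentile_acc: float


@dataclass
class RegressionResult:
    """OLS fit of a response on the participant-factor columns."""

    b0: float
    b: np.ndarray
    p_values: np.ndarray        # per factor coefficient
    p_intercept: float
    fitted: np.ndarray
    residuals: np.ndarray
    r_squared: float


@dataclass
class CorrelationResult:
    rho: float
    p: float
    significant: bool
    n_used: int
    threshold: float


@dataclass
class TrendResult:
    """Mann-Kendall trend statistics plus a least-squares slope."""

    S: int
    var_S: float
    z: float
    p: float
    direction: str              # "increasing" | "decreasing" | "none"
    ols_slope: float


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray([1 if g == POSITIVE_CLASS else 0 for g in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def loocv_svm(features: np.ndarray, labels,
              C: float = 1.0) -> ClassificationResult:
    """Leave-one-out linear SVM classification of the age groups.

    Each participant is predicted by a linear SVM (fixed ``C``, no
    within-fold tuning — there is no data to tune on at this sample size)
    trained on the remaining participants.  Predictors are standardized on
    each training fold (factor columns have arbitrary, typically tiny,
    scales after the unit-norm convention).  Accuracy is the fraction of
    correct held-out predictions; AUC is computed from the pooled held-out
    decision values.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _encode_labels(labels)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("features and labels disagree on sample count")
    decision = np.empty(n)
    predicted = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[train] - mu) / sd, y[train])
        margin = float(clf.decision_function(((X[i] - mu) / sd)[None, :])[0])
        # orient decision values so larger => positive class
        if clf.classes_[1] != 1:
            margin = -margin
        decision[i] = margin
        predicted[i] = int(clf.predict(((X[i] - mu) / sd)[None, :])[0])
    acc = float(np.mean(predicted == y))
    auc = float(roc_auc_score(y, decision))
    return ClassificationResult(
        factor_subset=tuple(range(X.shape[1])), auc=auc, acc=acc,
        predicted=predicted, decision_values=decision)


def subset_search(D: np.ndarray, labels,
                  max_size: int | None = None,
                  C: float = 1.0) -> list[ClassificationResult]:
    """Evaluate every non-empty subset of participant-factor columns.

    Singletons first identify the most discriminative components, then
    pairs, triplets and so forth; the returned list is sorted by AUC, then
    accuracy (ties broken by smaller subsets, then lexicographic order, so
    the ranking is deterministic).
    """
    from itertools import combinations

    D = np.asarray(D, dtype=float)
    R = D.shape[1]
    if max_size is None:
        max_size = R
    results = []
    for size in range(1, max_size + 1):
        for subset in combinations(range(R), size):
            res = loocv_svm(D[:, subset], labels, C=C)
            res.factor_subset = subset
            results.append(res)
    results.sort(key=lambda r: (-r.auc, -r.acc, len(r.factor_subset),
                                r.factor_subset))
    return results


def permutation_importance(D: np.ndarray, labels, subset, r: int,
                           n_perm: int = 100, seed: int = 0,
                           C: float = 1.0) -> PermutationResult:
    """Permutation test of one factor column's contribution to classification.

    Column ``r`` of the subset's feature matrix is permuted across
    participants ``n_perm`` times (other columns intact) and the classifier
    is re-run each time.  The reported percentile is the fraction of null
    values strictly below the unpermuted performance (ties counted half),
    times 100.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    subset = tuple(subset)
    if r not in subset:
        raise ValueError(f"factor {r} is not in subset {subset}")
    D = np.asarray(D, dtype=float)
    base = loocv_svm(D[:, subset], labels, C=C)
    col = subset.index(r)
    rng = np.random.default_rng(seed)
    null_auc = np.empty(n_perm)
    null_acc = np.empty(n_perm)
    feats = D[:, subset].copy()
    for b in range(n_perm):
        perm = rng.permutation(len(feats))
        feats_b = feats.copy()
        feats_b[:, col] = feats[perm, col]
        res = loocv_svm(feats_b, labels, C=C)
        null_auc[b] = res.auc
        null_acc[b] = res.acc
    return PermutationResult(
        factor_index=r, n_perm=n_perm, null_auc=null_auc, null_acc=null_acc,
        percentile_auc=_percentile(base.auc, null_auc),
        percentile_acc=_percentile(base.acc, null_acc))


def _percentile(value: float, null: np.ndarray) -> float:
    below = np.sum(null < value) + 0.5 * np.sum(null == value)
    return 100.0 * float(below) / len(null)


# ---------------------------------------------------------------------------
# Regression and correlation
# ---------------------------------------------------------------------------

def fit_regression(D: np.ndarray, response) -> RegressionResult:
    """OLS of a participant-level response on the factor columns.

    ``y_p = d_p b + b0 + eps_p`` with an intercept; coefficient p-values are
    two-sided t-tests.
    """
    D = np.asarray(D, dtype=float)
    y = np.asarray(response, dtype=float)
    P, R = D.shape
    if P <= R + 1:
        raise ValueError(f"need more than {R + 1} participants, got {P}")
    design = sm.add_constant(D, has_constant="raise")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank-deficient "
                                    "(collinear factor columns)")
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        b0=float(fit.params[0]), b=np.asarray(fit.params[1:]),
        p_values=np.asarray(fit.pvalues[1:]),
        p_intercept=float(fit.pvalues[0]),
        fitted=np.asarray(fit.fittedvalues),
        residuals=np.asarray(fit.resid),
        r_squared=float(fit.rsquared))


def correlate(factor_column, response, exclude=(), alpha: float = 0.05,
              n_comparisons: int = 1) -> CorrelationResult:
    """Pearson correlation with optional exclusion of outlying participants.

    ``exclude`` holds 0-based participant positions to drop before
    computing the correlation.  Significance is judged at the
    Bonferroni-corrected level ``alpha / n_comparisons``.
    """
    x = np.asarray(factor_column, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    keep = np.ones(len(x), dtype=bool)
    for i in exclude:
        keep[i] = False
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 retained pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.pearsonr(x, y)
    threshold = alpha / n_comparisons
    return CorrelationResult(rho=float(rho), p=float(p),
                             significant=bool(p < threshold),
                             n_used=len(x), threshold=threshold)


# ---------------------------------------------------------------------------
# Trend and group tests
# ---------------------------------------------------------------------------

def mann_kendall(values, alpha: float = 0.05) -> TrendResult:
    """Mann-Kendall test for a monotone trend over trials.

    ``S`` sums the signs of all pairwise later-minus-earlier differences;
    its variance is tie-corrected and the z statistic uses the usual
    continuity correction.  An OLS slope over the trial index accompanies
    the test as an effect-size summary.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 trials, got {n}")
    diff_signs = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff_signs, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    tie_term = np.sum(counts * (counts - 1) * (2 * counts + 5))
    var_S = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if S > 0:
        z = (S - 1) / np.sqrt(var_S)
    elif S < 0:
        z = (S + 1) / np.sqrt(var_S)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    if p < alpha:
        direction = "increasing" if S > 0 else "decreasing"
    else:
        direction = "none"
    slope = float(np.polyfit(np.arange(1, n + 1), x, 1)[0])
    return TrendResult(S=S, var_S=float(var_S), z=float(z), p=float(p),
                       direction=direction, ols_slope=slope)


def group_difference_test(factor_column, groups, n_comparisons: int = 1,
                          alpha: float = 0.05, welch: bool = False):
    """Independent two-sample t-test of a factor column between age groups.

    Pooled-variance by default (``welch`` switches to unequal variances);
    significance at the Bonferroni-corrected ``alpha / n_comparisons``.
    Returns ``(t, p, significant)``.
    """
    x = np.asarray(factor_column, dtype=float)
    groups = np.asarray(groups)
    ya = x[groups == "YA"]
    oa = x[groups == "OA"]
    if len(ya) < 2 or len(oa) < 2:
        raise ValueError("need at least two participants per group")
    t, p = stats.ttest_ind(oa, ya, equal_var=not welch)
    return float(t), float(p), bool(p < alpha / n_comparisons)
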