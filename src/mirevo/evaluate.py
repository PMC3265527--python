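"""Validation metrics, cross-validation, and feature ranking.

The predictor is two-stage, so its confusion bookkeeping charges the
ab-initio stage's resolved negatives (TN_ab) and missed positives (FN_ab)
to the overall score alongside the ML stage's TP/FP/TN/FN:

    Q  = (TP_ML + TN_ML + TN_ab) / (all six counts)
    SP = (TN_ML + TN_ab) / (FP_ML + TN_ML + TN_ab)
    SE = TP_ML / (TP_ML + FN_ML + FN_ab)

For gene-level (indirect) validation, where only expression fold changes
support a target call, sensitivity and precision are computed against the
selected set SS of affected genes.

Feature ranking combines a per-feature F-score,
``|mu_P - mu_N| / |sigma_P - sigma_N|`` (population standard deviations,
implemented exactly as stated; a conventional ``sigma_P + sigma_N``
denominator is available behind a flag), with a correlation ranking: in
each column of the absolute feature-correlation matrix features are ranked
ascending (1 = least correlated), the ranks are summed per feature, and
the F-score ranking (1 = most discriminative) plus the correlation ranking
give the final cumulative rank (ties share a rank).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    tp_ml: int = 0
    fp_ml: int = 0
    tn_ml: int = 0
    fn_ml: int = 0
    tn_ab: int = 0
    fn_ab: int = 0

    def __post_init__(self):
        if min(self.tp_ml, self.fp_ml, self.tn_ml, self.fn_ml, self.tn_ab, self.fn_ab) < 0:
            raise ValueError("confusion counts must be >= 0")


@dataclass(frozen=True)
class MetricReport:
    accuracy: float | None
    specificity: float | None
    sensitivity: float | None
    precision: float | None = None
    ci_half_width: float | None = None


def composite_metrics(c: ConfusionCounts) -> MetricReport:
    """Two-stage accuracy, specificity, sensitivity (and precision).

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never silently as 0.
    """
    tn_all = c.tn_ml + c.tn_ab
    fn_all = c.fn_ml + c.fn_ab
    total = c.tp_ml + c.fp_ml + tn_all + fn_all

    def ratio(num, den):
        return num / den if den > 0 else None

    return MetricReport(
        accuracy=ratio(c.tp_ml + tn_all, total),
        specificity=ratio(tn_all, c.fp_ml + tn_all),
        sensitivity=ratio(c.tp_ml, c.tp_ml + fn_all),
        precision=ratio(c.tp_ml, c.tp_ml + c.fp_ml),
    )


def indirect_metrics(predicted_genes, evaluated_genes, selected_set):
    """Gene-level (sensitivity, precision) against the selected set SS.

    ``sensitivity = |predicted ∩ SS| / |SS|``;
    ``precision = |predicted ∩ SS| / |predicted|``.  SS must be a subset of
    the evaluated genes; an empty SS or empty prediction leaves the
    respective metric undefined (``None``).
    """
    predicted = set(predicted_genes)
    evaluated = set(evaluated_genes)
    ss = set(selected_set)
    if not ss <= evaluated:
        raise ValueError("selected set must be a subset of the evaluated genes")
    hit = len(predicted & ss)
    sensitivity = hit / len(ss) if ss else None
    precision = hit / len(predicted) if predicted else None
    return sensitivity, precision


def fscore(pos_values, neg_values, standard: bool = False) -> float | None:
    """Per-feature class-separability score ``|mu_P-mu_N| / |sigma_P-sigma_N|``.

    Population standard deviations.  When the denominator vanishes the
    score is undefined (``None``).  ``standard=True`` switches to the
    conventional ``sigma_P + sigma_N`` denominator for comparison.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    num = abs(pos.mean() - neg.mean())
    sp, sn = pos.std(), neg.std()
    den = sp + sn if standard else abs(sp - sn)
    if num < 1e-12:
        return 0.0  # no mean separation: no discriminative power
    if den < 1e-12:
        return None
    return num / den


def correlation_ranking(feature_matrix, method: str = "pearson") -> np.ndarray:
    """Cumulative correlation rank per feature (lower = less redundant).

    Within each column of the absolute correlation matrix the off-diagonal
    entries are ranked ascending (rank 1 = lowest correlation, ties share
    the mean rank); each feature's ranks are summed across columns.
    Zero-variance features have undefined correlations and are ranked last
    in every column.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 2 features and >= 3 records")
    p = X.shape[1]
    if method == "spearman":
        corr = stats.spearmanr(X).statistic
        corr = np.atleast_2d(corr)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
    corr = np.abs(corr)
    sums = np.zeros(p)
    for j in range(p):
        col = np.array([corr[i, j] for i in range(p) if i != j])
        idx = [i for i in range(p) if i != j]
        # undefined correlations rank last: replace NaN with +inf
        col = np.where(np.isnan(col), np.inf, col)
        ranks = stats.rankdata(col, method="average")
        for i, r in zip(idx, ranks):
            sums[i] += r
    return sums


def cumulative_feature_ranking(f_scores, correlation_sums):
    """Final cumulative rank combining F-score and correlation rankings.

    ``f_scores``: per-feature F-score (``None``/NaN allowed, ranked last);
    ``correlation_sums``: the per-feature summed column ranks.  The F-score
    ranking (1 = highest F-score) is converted to ranks, the correlation
    sums likewise (1 = lowest sum), the two ranks are added, and features
    are ranked ascending by the total; tied totals share the same (minimum)
    final rank.

    Returns ``(final_rank, fscore_rank, corr_rank)`` integer arrays.
    """
    fs = np.array(
        [math.nan if v is None else float(v) for v in f_scores], dtype=float
    )
    cs = np.asarray(correlation_sums, dtype=float)
    if fs.shape != cs.shape:
        raise ValueError("f_scores and correlation_sums must align")
    fs_filled = np.where(np.isnan(fs), -np.inf, fs)
    fscore_rank = stats.rankdata(-fs_filled, method="min")
    corr_rank = stats.rankdata(cs, method="min")
    total = fscore_rank + corr_rank
    final = stats.rankdata(total, method="min")
    return final.astype(int), fscore_rank.astype(int), corr_rank.astype(int)


def cross_validate(
    records,
    train_and_score,
    k_folds: int = 20,
    runs: int = 10,
    rng_seed: int = 0,
    alpha: float = 0.05,
):
    """miRNA-disjoint k-fold cross-validation repeated over several runs.

    ``train_and_score(train_records, test_records) -> float`` evaluates one
    fold.  Folds partition *miRNAs*, never records, so no miRNA is shared
    between training and held-out data.  Returns ``(mean, ci_half_width)``
    where the confidence interval is the t-interval over the per-run mean
    scores at significance ``alpha``.
    """
    ids = sorted({r.mirna_id for r in records})
    if len(ids) < k_folds:
        raise ValueError(
            f"only {len(ids)} distinct miRNAs for {k_folds} folds; use a smaller k"
        )
    rng = np.random.default_rng(rng_seed)
    run_means = []
    for _ in range(runs):
        order = list(ids)
        rng.shuffle(order)
        folds = [order[i::k_folds] for i in range(k_folds)]
        scores = []
        for fold_ids in folds:
            fold_set = set(fold_ids)
            train = [r for r in records if r.mirna_id not in fold_set]
            test = [r for r in records if r.mirna_id in fold_set]
            if not test or not train:
                continue
            scores.append(train_and_score(train, test))
        run_means.append(float(np.mean(scores)))
    mean = float(np.mean(run_means))
    if len(run_means) < 2 or np.std(run_means) == 0:
        return mean, 0.0
    sem = stats.sem(run_means)
    half = float(sem * stats.t.ppf(1 - alpha / 2, len(run_means) - 1))
    return mean, half
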