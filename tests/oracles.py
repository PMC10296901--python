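"""Independent brute-force oracles used by the metric and acceptance tests.

These deliberately avoid every code path in gdalink.metrics: AUC by O(P*N)
pair counting, AP by an explicit loop over distinct thresholds, and Youden
by exhaustive threshold search.
"""

import numpy as np


def mann_whitney_auc(scores, labels):
    """P(score_pos > score_neg) + 0.5 * P(tie), by explicit pair counting."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def step_sum_ap(scores, labels):
    """AP = sum over distinct thresholds of (R_n - R_{n-1}) * P_n."""
    p_total = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        recall = tp / p_total
        precision = tp / pred.sum()
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def exhaustive_youden(scores, labels):
    """Try every candidate threshold (+inf plus each distinct score)."""
    best_t, best_j = np.inf, 0.0
    p = labels.sum()
    n = len(labels) - p
    for t in [np.inf] + sorted(set(scores), reverse=True):
        pred = scores >= t
        tpr = (pred & (labels == 1)).sum() / p
        fpr = (pred & (labels == 0)).sum() / n
        if tpr - fpr > best_j:
            best_t, best_j = t, tpr - fpr
    return best_t, best_j


def random_instances(n_instances=100, n=200, seed=123):
    """Seeded random score/label instances with heavy score ties."""
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 1, 0
        scores = np.round(rng.random(n), 2)
        yield scores, labels
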