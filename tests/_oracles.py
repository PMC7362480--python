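"""Independent brute-force oracles for ranking metrics.

Deliberately slow and explicit: confusion counts are recomputed from
scratch at every distinct threshold by direct iteration, and ROC AUC is
additionally available as the Mann–Whitney pairwise statistic.  These never
share code with the library implementations they check.
"""

from __future__ import annotations


def brute_force_pr_auc(scores, labels) -> float:
    """Average precision via explicit threshold enumeration."""
    thresholds = sorted(set(scores), reverse=True)
    n_pos = sum(labels)
    auc = 0.0
    prev_recall = 0.0
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        precision = tp / (tp + fp)
        recall = tp / n_pos
        auc += (recall - prev_recall) * precision
        prev_recall = recall
    return auc


def brute_force_roc_auc(scores, labels) -> float:
    """Mann–Whitney statistic: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
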