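"""Benchmark construction and ranking metrics.

Benchmarks come in two shapes.  The *pairwise* test set scores chemical
pairs: pairs of actives bound to a common target or evolutionarily related
targets are positives, and each active is additionally paired with randomly
sampled background molecules (fourfold by default) to form negatives.  The
*pointwise* test set scores individual molecules: the actives of a target
against randomly sampled background molecules, again at a fourfold ratio.

Actives are defined by an affinity filter: a (molecule, target) interaction
counts as active only when at least one of its measurements (Ki, IC50, Kd or
EC50) is strictly below 100 nM, excluding promiscuous binders.

Ranking quality is summarized by the precision–recall curve (area computed
as step-wise average precision, with tied scores grouped into a single
threshold) and the ROC curve (trapezoidal area).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AFFINITY_TYPES = ("Ki", "IC50", "Kd", "EC50")


@dataclass(frozen=True)
class InteractionRecord:
    """One compound–target affinity measurement, value in nM."""

    mol_id: str
    target_id: str
    affinity_type: str
    value_nM: float

    def __post_init__(self) -> None:
        if self.affinity_type not in AFFINITY_TYPES:
            raise ValueError(f"affinity_type must be one of {AFFINITY_TYPES}, "
                             f"got {self.affinity_type!r}")
        if not (self.value_nM > 0):
            raise ValueError(f"value_nM must be positive, got {self.value_nM}")


@dataclass
class RankedPredictions:
    """Scored, labelled items ready for curve computation."""

    items: list[tuple[str, float | None, int]]

    @property
    def positive_count(self) -> int:
        return sum(1 for _, _, y in self.items if y)

    @property
    def negative_count(self) -> int:
        return sum(1 for _, _, y in self.items if not y)

    def with_scores(self, scores: Mapping[str, float]) -> "RankedPredictions":
        return RankedPredictions(
            [(i, float(scores[i]), y) for i, _, y in self.items]
        )


@dataclass
class CurveResult:
    points: list[tuple[float, float]]
    auc: float
    kind: str  # "pr" or "roc"


def load_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read a TSV with columns mol_id, target_id, affinity_type, value_nM."""
    df = pd.read_csv(path, sep="\t", dtype={"mol_id": str, "target_id": str,
                                            "affinity_type": str})
    required = {"mol_id", "target_id", "affinity_type", "value_nM"}
    if not required <= set(df.columns):
        raise ValueError(f"interaction table must have columns {sorted(required)}")
    return [
        InteractionRecord(r.mol_id, r.target_id, r.affinity_type, float(r.value_nM))
        for r in df.itertuples(index=False)
    ]


def filter_actives(records: Sequence[InteractionRecord],
                   threshold_nM: float = 100.0) -> list[InteractionRecord]:
    """Keep a (mol, target) interaction iff ANY of its measurements is
    strictly below ``threshold_nM``.

    The four affinity types are treated disjunctively: one sub-threshold Kd
    keeps the pair even if its Ki is weak.  All of a kept pair's records are
    returned, preserving input order, so the filter is idempotent.
    """
    if not (threshold_nM > 0):
        raise ValueError("threshold_nM must be positive")
    keep: set[tuple[str, str]] = {
        (r.mol_id, r.target_id) for r in records if r.value_nM < threshold_nM
    }
    return [r for r in records if (r.mol_id, r.target_id) in keep]


def actives_by_target(records: Sequence[InteractionRecord]) -> dict[str, list[str]]:
    """Unique active molecules per target, in first-seen order."""
    out: dict[str, list[str]] = {}
    for r in records:
        mols = out.setdefault(r.target_id, [])
        if r.mol_id not in mols:
            mols.append(r.mol_id)
    return out


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def build_pair_test_set(
    actives: Mapping[str, Sequence[str]],
    catalog,
    background: Sequence[str],
    neg_ratio: int = 4,
    seed: int = 0,
    level: str | None = None,
) -> list:
    """Pairwise benchmark: positive and negative chemical pairs.

    Positives: all unordered pairs of molecules active on a common target or
    on evolutionarily related targets (related at ``level``, or at any
    catalog level when ``level`` is None).  Negatives: each active paired
    with ``neg_ratio`` background molecules drawn without replacement within
    that active's draw (with replacement across actives); a draw that lands
    on a molecule active on a related target is resampled, so negatives are
    unlikely to bind a common or related target.
    """
    from .models import ChemicalPair  # local import to avoid a cycle
    from .evoann import related_targets

    if neg_ratio < 1:
        raise ValueError("neg_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    levels = [level] if level is not None else list(catalog.levels)

    mol_targets: dict[str, set[str]] = {}
    for t, mols in actives.items():
        for m in mols:
            mol_targets.setdefault(m, set()).add(t)
    active_mols = sorted(mol_targets)
    if sum(len(v) >= 2 for v in actives.values()) == 0 and len(active_mols) < 2:
        raise ValueError("need at least two active molecules")

    # positives: expand each molecule's targets to related targets, pair
    # molecules whose expansions intersect their partner's target set
    related_sets: dict[str, set[str]] = {}
    for m in active_mols:
        rel: set[str] = set()
        for t in mol_targets[m]:
            for lv in levels:
                rel |= related_targets(catalog, t, lv)
        related_sets[m] = rel

    positives: list = []
    seen: set[tuple[str, str]] = set()
    for i, a in enumerate(active_mols):
        for b in active_mols[i + 1:]:
            if related_sets[a] & mol_targets[b]:
                key = _pair_key(a, b)
                if key not in seen:
                    seen.add(key)
                    positives.append(ChemicalPair(key[0], key[1], {"pair": True}, "test"))

    # negatives: per-active background draw, excluding related actives
    bg = list(background)
    negatives: list = []
    for a in active_mols:
        excluded = {m for m in active_mols if related_sets[a] & mol_targets[m]}
        pool = [m for m in bg if m not in excluded and m != a]
        if len(pool) < neg_ratio:
            raise ValueError(
                f"background pool too small for {a!r}: need {neg_ratio}, "
                f"have {len(pool)} after exclusions")
        partners = rng.choice(len(pool), size=neg_ratio, replace=False)
        for j in partners:
            key = _pair_key(a, pool[j])
            negatives.append(ChemicalPair(key[0], key[1], {"pair": False}, "test"))
    return positives + negatives


def build_pointwise_test_set(
    actives: Sequence[str],
    background: Sequence[str],
    neg_ratio: int = 4,
    seed: int = 0,
) -> RankedPredictions:
    """Pointwise benchmark skeleton: labelled molecules awaiting scores.

    Emits every active (label 1) plus ``neg_ratio`` background molecules per
    active (label 0), drawn without replacement from the background pool.
    """
    if len(actives) == 0:
        raise ValueError("need at least one active molecule")
    if neg_ratio < 1:
        raise ValueError("neg_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    active_set = set(actives)
    pool = [m for m in background if m not in active_set]
    n_neg = neg_ratio * len(actives)
    if len(pool) < n_neg:
        raise ValueError(f"background pool too small: need {n_neg}, have {len(pool)}")
    idx = rng.choice(len(pool), size=n_neg, replace=False)
    items: list[tuple[str, float | None, int]] = [(m, None, 1) for m in actives]
    items += [(pool[i], None, 0) for i in idx]
    return RankedPredictions(items)


def _sweep(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP over descending score thresholds, ties grouped."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # last index of each tied group
    distinct = np.where(np.diff(s) != 0)[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(1 - y)[cut]
    return tp.astype(float), fp.astype(float)


def pr_curve(r: RankedPredictions) -> CurveResult:
    """Precision–recall curve; area = step-wise average precision.

    Precision = TP/(TP+FP) and Recall = TP/(TP+FN), computed at every
    distinct score threshold swept from the highest score down; the area is
    Σ (R_i − R_{i−1})·P_i.  Tied scores enter a single threshold.
    """
    scores = np.array([s for _, s, _ in r.items], dtype=float)
    labels = np.array([y for _, _, y in r.items], dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("both classes must be present for a PR curve")
    tp, fp = _sweep(scores, labels)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    auc = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
    points = list(zip(recall.tolist(), precision.tolist()))
    return CurveResult(points=points, auc=auc, kind="pr")


def roc_curve(r: RankedPredictions) -> CurveResult:
    """ROC curve (FPR vs sensitivity); area by the trapezoid rule."""
    scores = np.array([s for _, s, _ in r.items], dtype=float)
    labels = np.array([y for _, _, y in r.items], dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    tp, fp = _sweep(scores, labels)
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return CurveResult(points=points, auc=auc, kind="roc")


def evaluate_methods(
    scorers: Mapping[str, Callable[[str, Sequence[str]], Sequence[float]]],
    test_sets: Mapping[str, RankedPredictions],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-target PR/ROC AUC for each named scorer on identical item sets.

    ``scorers`` maps a method name to a callable ``(target_id, mol_ids) ->
    scores``.  A scorer failure on a target is recorded as missing (NaN) and
    the run continues.  Returns a tidy frame with one row per (method,
    target).
    """
    if not scorers:
        raise ValueError("need at least one scorer")
    rows = []
    for method, scorer in scorers.items():
        for target, rp in test_sets.items():
            mol_ids = [i for i, _, _ in rp.items]
            try:
                scores = scorer(target, mol_ids)
                scored = rp.with_scores(dict(zip(mol_ids, scores)))
                pr_auc = pr_curve(scored).auc
                roc_auc = roc_curve(scored).auc
            except Exception:
                pr_auc = roc_auc = float("nan")
            rows.append((method, target, rp.positive_count, rp.negative_count,
                         pr_auc, roc_auc))
    return pd.DataFrame(
        rows, columns=["method", "target", "n_pos", "n_neg", "pr_auc", "roc_auc"]
    )


def summarize_auc_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of the per-target AUCs for each method."""
    return (
        table.groupby("method")[["pr_auc", "roc_auc"]]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
    )
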