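"""Evolutionary chemical binding similarity (ECBS) models.

The method learns a *binding* similarity between chemical compounds: a
binary classifier is trained to distinguish evolutionarily related chemical
pairs (ERCPs — pairs of compounds whose targets are identical or share an
evolutionary annotation) from randomly chosen negative pairs.  One classifier
is trained per annotation level; their output scores are stacked by a
secondary classifier (ensECBS) into a final pair score in [0, 1], read as
the probability that the two compounds bind a common or related target.

The target-specific variant (TS-ensECBS) restricts the ERCP definition, at
every level, to targets evolutionarily related to one predefined virtual-
screening (VS) target.  A query molecule is scored against the VS target's
known actives and assigned the maximum pair score, so the output directly
ranks a chemical library for binding to that target.

Pairs are featurized order-invariantly as the concatenation of the
elementwise AND and elementwise XOR of the two fingerprints (shared bits and
differing bits).  The default level classifier is a bagged decision-tree
ensemble (random forest) behind a pluggable factory; the stacker is a
logistic regression over the level scores, trained on a held-out fraction of
the pairs so the stacking inputs are out-of-sample.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .bench import InteractionRecord, filter_actives, pr_curve, RankedPredictions
from .chemreg import Molecule, MoleculeSet, tanimoto
from .evoann import AnnotationCatalog, related_targets


class LeakageError(RuntimeError):
    """Training pairs leaked into the stacking (held-out) split."""


@dataclass
class ChemicalPair:
    """Unordered molecule pair with per-level ERCP labels and a split tag."""

    mol_a: str
    mol_b: str
    labels: dict[str, bool] = field(default_factory=dict)
    split: str = "train"

    def __post_init__(self) -> None:
        if self.mol_a == self.mol_b:
            raise ValueError(f"a pair cannot pair {self.mol_a!r} with itself")
        if self.mol_a > self.mol_b:
            self.mol_a, self.mol_b = self.mol_b, self.mol_a

    @property
    def key(self) -> tuple[str, str]:
        return (self.mol_a, self.mol_b)


def pair_features(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Order-invariant pair featurization: [AND block | XOR block]."""
    fa = np.asarray(fa, dtype=np.uint8)
    fb = np.asarray(fb, dtype=np.uint8)
    if fa.shape != fb.shape:
        raise ValueError(f"fingerprint length mismatch: {fa.shape} vs {fb.shape}")
    return np.concatenate([fa & fb, fa ^ fb])


def pair_feature_matrix(pairs: Sequence[ChemicalPair],
                        fingerprints: Mapping[str, np.ndarray]) -> np.ndarray:
    if not pairs:
        raise ValueError("no pairs to featurize")
    return np.stack([pair_features(fingerprints[p.mol_a], fingerprints[p.mol_b])
                     for p in pairs])


def _mol_targets(interactions: Sequence[InteractionRecord]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for r in interactions:
        out.setdefault(r.mol_id, set()).add(r.target_id)
    return out


def _level_labels(
    mol_targets: Mapping[str, set[str]],
    catalog: AnnotationCatalog,
    levels: Sequence[str],
    restrict_map: Mapping[str, set[str]] | None,
) -> dict[str, dict[str, set[str]]]:
    """Per level, each molecule's targets expanded to their related set.

    When ``restrict_map`` is given (target-specific mode) both the targets
    considered and their expansions are intersected with the allowed set for
    that level, so ERCPs are only defined within the VS target's relatives.
    """
    expansions: dict[str, dict[str, set[str]]] = {lv: {} for lv in levels}
    for lv in levels:
        allowed = restrict_map.get(lv) if restrict_map else None
        for m, targets in mol_targets.items():
            use = targets if allowed is None else targets & allowed
            rel: set[str] = set()
            for t in use:
                r = related_targets(catalog, t, lv)
                rel |= (r if allowed is None else r & allowed)
            expansions[lv][m] = rel
    return expansions


def _pair_is_ercp(expansion: Mapping[str, set[str]],
                  mol_targets: Mapping[str, set[str]],
                  restrict: set[str] | None, a: str, b: str) -> bool:
    tb = mol_targets.get(b, set())
    if restrict is not None:
        tb = tb & restrict
    return bool(expansion.get(a, set()) & tb)


def build_training_pairs(
    interactions: Sequence[InteractionRecord],
    catalog: AnnotationCatalog,
    level: str,
    background: Sequence[str],
    neg_ratio: int = 4,
    seed: int = 0,
    restrict_map: Mapping[str, set[str]] | None = None,
    label_levels: Sequence[str] | None = None,
    max_positive_pairs: int | None = None,
) -> list[ChemicalPair]:
    """Training pairs for one annotation level.

    Positives are all unordered pairs of active molecules that form an ERCP
    at ``level``; every pair is additionally labelled at every level in
    ``label_levels`` (default: all catalog levels).  Negatives pair each
    active with ``neg_ratio`` background molecules, excluding any molecule
    that itself forms an ERCP with the active at ``level``.  Fully
    reproducible under ``seed``.
    """
    if neg_ratio < 1:
        raise ValueError("neg_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    levels = list(label_levels) if label_levels is not None else list(catalog.levels)
    if level not in levels:
        levels = [level] + levels

    mol_targets = _mol_targets(interactions)
    if restrict_map and level in restrict_map:
        allowed = restrict_map[level]
        actives = sorted(m for m, ts in mol_targets.items() if ts & allowed)
    else:
        actives = sorted(mol_targets)
    if len(actives) < 2:
        raise ValueError("need at least two active molecules to form pairs")

    expansions = _level_labels(mol_targets, catalog, levels, restrict_map)

    def labels_for(a: str, b: str) -> dict[str, bool]:
        return {
            lv: _pair_is_ercp(expansions[lv], mol_targets,
                              restrict_map.get(lv) if restrict_map else None, a, b)
            for lv in levels
        }

    positives: list[ChemicalPair] = []
    for i, a in enumerate(actives):
        for b in actives[i + 1:]:
            lab = labels_for(a, b)
            if lab[level]:
                positives.append(ChemicalPair(a, b, lab, "train"))
    if max_positive_pairs is not None and len(positives) > max_positive_pairs:
        idx = rng.choice(len(positives), size=max_positive_pairs, replace=False)
        positives = [positives[i] for i in sorted(idx)]

    negatives: list[ChemicalPair] = []
    for a in actives:
        exp_a = expansions[level][a]
        pool = [
            m for m in background
            if m != a and not _pair_is_ercp(
                expansions[level], mol_targets,
                restrict_map.get(level) if restrict_map else None, a, m)
        ]
        if len(pool) < neg_ratio:
            raise ValueError(
                f"background pool too small for active {a!r}: need {neg_ratio} "
                f"non-ERCP partners, have {len(pool)}")
        for j in rng.choice(len(pool), size=neg_ratio, replace=False):
            negatives.append(ChemicalPair(a, pool[j], labels_for(a, pool[j]), "train"))
    return positives + negatives


def default_classifier(seed: int, n_estimators: int = 100):
    """Bagged decision-tree ensemble: the default probabilistic pair scorer."""
    return RandomForestClassifier(
        n_estimators=n_estimators, min_samples_leaf=2,
        random_state=seed, n_jobs=1,
    )


@dataclass
class LevelModel:
    level: str
    classifier: object
    training_meta: dict = field(default_factory=dict)

    def score(self, X: np.ndarray) -> np.ndarray:
        proba = self.classifier.predict_proba(X)
        return proba[:, list(self.classifier.classes_).index(1)]


def train_level_model(
    level: str,
    pairs: Sequence[ChemicalPair],
    features: np.ndarray,
    seed: int = 0,
    classifier_factory: Callable[[int], object] | None = None,
) -> LevelModel:
    """Fit one per-level ERCP classifier on the pair-feature matrix.

    Both classes must be present.  ``training_meta`` records the seed, class
    counts, the training pair keys (for leakage audits) and the in-sample PR
    AUC as a separation diagnostic.
    """
    y = np.array([int(p.labels[level]) for p in pairs])
    if len(set(y.tolist())) < 2:
        raise ValueError(f"level {level!r}: training pairs contain a single class")
    clf = (classifier_factory or default_classifier)(seed)
    clf.fit(features, y)
    proba = clf.predict_proba(features)[:, list(clf.classes_).index(1)]
    train_pr = pr_curve(RankedPredictions(
        [(f"p{i}", float(s), int(t)) for i, (s, t) in enumerate(zip(proba, y))]
    )).auc
    meta = {
        "seed": seed,
        "n_pos": int(y.sum()),
        "n_neg": int(len(y) - y.sum()),
        "train_pr_auc": train_pr,
        "pair_keys": sorted(p.key for p in pairs),
    }
    return LevelModel(level=level, classifier=clf, training_meta=meta)


@dataclass
class EnsembleModel:
    level_models: list[LevelModel]
    stacker: object
    scheme: str = "maccs"

    def level_scores(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([lm.score(X) for lm in self.level_models])

    def score_features(self, X: np.ndarray) -> np.ndarray:
        Z = self.level_scores(X)
        proba = self.stacker.predict_proba(Z)
        return proba[:, list(self.stacker.classes_).index(1)]


def train_ensemble(
    level_models: Sequence[LevelModel],
    stacking_pairs: Sequence[ChemicalPair],
    fingerprints: Mapping[str, np.ndarray],
    seed: int = 0,
    scheme: str = "maccs",
) -> EnsembleModel:
    """Stack the level-model scores with a secondary classifier.

    The stacking pairs must be held out from every level model's training
    pairs (split tags plus an explicit pair-key audit); overlap raises
    :class:`LeakageError`.  A stacking pair counts as positive when it is an
    ERCP at any labelled level.
    """
    if not level_models:
        raise ValueError("need at least one level model")
    if not stacking_pairs:
        raise ValueError("need stacking pairs to train the ensemble")
    trained_keys: set[tuple[str, str]] = set()
    for lm in level_models:
        trained_keys.update(map(tuple, lm.training_meta.get("pair_keys", [])))
    bad_split = [p.key for p in stacking_pairs if p.split == "train"]
    overlap = [p.key for p in stacking_pairs if p.key in trained_keys]
    if bad_split or overlap:
        raise LeakageError(
            f"stacking pairs overlap level-model training pairs "
            f"(split-tagged: {len(bad_split)}, key overlap: {len(overlap)})")
    X = pair_feature_matrix(stacking_pairs, fingerprints)
    Z = np.column_stack([lm.score(X) for lm in level_models])
    y = np.array([int(any(p.labels.values())) for p in stacking_pairs])
    if len(set(y.tolist())) < 2:
        raise ValueError("stacking pairs contain a single class")
    stacker = LogisticRegression(max_iter=1000, random_state=seed)
    stacker.fit(Z, y)
    return EnsembleModel(level_models=list(level_models), stacker=stacker,
                         scheme=scheme)


def score_pair(model: EnsembleModel, fa: np.ndarray, fb: np.ndarray) -> float:
    """Ensemble similarity score in [0, 1] for one pair of fingerprints."""
    X = pair_features(fa, fb)[None, :]
    return float(model.score_features(X)[0])


@dataclass
class TSConfig:
    """Configuration for training a target-specific ensemble model."""

    levels: tuple[str, ...] | None = None  # default: catalog levels
    scheme: str = "maccs"
    neg_ratio: int = 4
    affinity_threshold_nM: float = 100.0
    warn_threshold: int = 10          # advisory minimum active count
    stack_fraction: float = 0.25      # held-out fraction feeding the stacker
    max_positive_pairs: int = 2000
    n_estimators: int = 100


@dataclass
class TSModel:
    """Target-specific ensemble model plus its reference active set."""

    vs_target: str
    ensemble: EnsembleModel
    actives: MoleculeSet
    config: TSConfig = field(default_factory=TSConfig)
    training_meta: dict = field(default_factory=dict)


def _split_pairs(pairs: list[ChemicalPair], stack_fraction: float,
                 rng: np.random.Generator) -> tuple[list[ChemicalPair], list[ChemicalPair]]:
    """Stratified split into level-training ('train') and stacking ('test')."""
    pos = [p for p in pairs if any(p.labels.values())]
    neg = [p for p in pairs if not any(p.labels.values())]
    train, stack = [], []
    for group in (pos, neg):
        idx = rng.permutation(len(group))
        n_stack = max(1, int(round(stack_fraction * len(group))))
        stack_idx = set(idx[:n_stack].tolist())
        for i, p in enumerate(group):
            if i in stack_idx:
                stack.append(replace(p, split="test"))
            else:
                train.append(replace(p, split="train"))
    return train, stack


def train_ts_model(
    vs_target: str,
    interactions: Sequence[InteractionRecord],
    catalog: AnnotationCatalog,
    molecules: MoleculeSet,
    background: Sequence[str] | None = None,
    config: TSConfig = TSConfig(),
    seed: int = 0,
) -> TSModel:
    """Train a TS-ensECBS model for one virtual-screening target.

    Interactions are affinity-filtered (strictly below the configured nM
    threshold); the VS target must retain at least one active.  For each
    annotation level the ERCP definition is restricted to targets related to
    the VS target at that level; per-level classifiers are trained on a
    'train' split of the pairs and the stacker on the held-out split.  The
    VS target's actives are stored as the reference set for query scoring.
    """
    import warnings

    rng = np.random.default_rng(seed)
    active_records = filter_actives(interactions, config.affinity_threshold_nM)
    mol_targets = _mol_targets(active_records)
    target_actives = sorted(m for m, ts in mol_targets.items() if vs_target in ts)
    if vs_target not in catalog.annotations:
        raise KeyError(f"unknown VS target {vs_target!r}")
    if not target_actives:
        raise ValueError(f"VS target {vs_target!r} has no actives after "
                         f"affinity filtering")
    if len(target_actives) < config.warn_threshold:
        warnings.warn(
            f"VS target {vs_target!r} has only {len(target_actives)} actives "
            f"(advisory minimum {config.warn_threshold}); the model may be "
            f"unreliable", UserWarning)

    levels = tuple(config.levels) if config.levels else tuple(catalog.levels)
    restrict_map = {lv: related_targets(catalog, vs_target, lv) for lv in levels}

    by_id = molecules.by_id()
    fingerprints = {m.mol_id: m.fingerprint(config.scheme) for m in molecules}
    if background is None:
        related_all: set[str] = set()
        for rel in restrict_map.values():
            related_all |= rel
        background = sorted(
            m for m in by_id
            if not (mol_targets.get(m, set()) & related_all)
        )

    level_models: list[LevelModel] = []
    stack_pool: dict[tuple[str, str], ChemicalPair] = {}
    trained_keys: set[tuple[str, str]] = set()
    for i, lv in enumerate(levels):
        pairs = build_training_pairs(
            active_records, catalog, lv, background,
            neg_ratio=config.neg_ratio,
            seed=int(rng.integers(2**31)),
            restrict_map=restrict_map, label_levels=levels,
            max_positive_pairs=config.max_positive_pairs,
        )
        train_part, stack_part = _split_pairs(pairs, config.stack_fraction, rng)
        X = pair_feature_matrix(train_part, fingerprints)
        lm = train_level_model(
            lv, train_part, X, seed=int(rng.integers(2**31)),
            classifier_factory=lambda s: default_classifier(s, config.n_estimators),
        )
        level_models.append(lm)
        trained_keys.update(p.key for p in train_part)
        for p in stack_part:
            stack_pool.setdefault(p.key, p)

    stacking_pairs = [p for p in stack_pool.values() if p.key not in trained_keys]
    ensemble = train_ensemble(level_models, stacking_pairs, fingerprints,
                              seed=int(rng.integers(2**31)), scheme=config.scheme)
    actives_set = MoleculeSet(
        [by_id[m] for m in target_actives if m in by_id],
        provenance=f"actives of {vs_target}",
    )
    if len(actives_set) == 0:
        raise ValueError(f"no fingerprints available for actives of {vs_target!r}")
    meta = {
        "seed": seed,
        "levels": list(levels),
        "n_actives": len(actives_set),
        "n_stacking_pairs": len(stacking_pairs),
    }
    return TSModel(vs_target=vs_target, ensemble=ensemble, actives=actives_set,
                   config=config, training_meta=meta)


def score_chemicals(ts: TSModel, queries: Iterable[Molecule]) -> pd.DataFrame:
    """Score each query with the maximum pair score over the reference actives.

    Returns a score table with one row per query: mol_id, score (the maximum
    TS-ensECBS pair score), best_reference (argmax; ties resolved to the
    lexicographically smallest reference id) and duplicate_of_reference (set
    when the query's canonical key equals a reference's — the score is still
    reported, flagged for audit).
    """
    refs = sorted(ts.actives.molecules, key=lambda m: m.mol_id)
    if not refs:
        raise ValueError("reference active set is empty")
    scheme = ts.config.scheme
    ref_fps = np.stack([m.fingerprint(scheme) for m in refs])
    ref_keys = {m.canonical_key for m in refs if m.canonical_key}
    rows = []
    for q in queries:
        fq = q.fingerprint(scheme)
        X = np.concatenate([ref_fps & fq, ref_fps ^ fq], axis=1)
        scores = ts.ensemble.score_features(X)
        best = int(np.argmax(scores))  # first occurrence = smallest ref id
        rows.append((
            q.mol_id, float(scores[best]), refs[best].mol_id,
            bool(q.canonical_key and q.canonical_key in ref_keys),
        ))
    return pd.DataFrame(
        rows, columns=["mol_id", "score", "best_reference", "duplicate_of_reference"]
    )


def score_chemical(ts: TSModel, query: Molecule) -> tuple[float, str]:
    """Maximum pair score of ``query`` against the reference actives."""
    row = score_chemicals(ts, [query]).iloc[0]
    return float(row["score"]), str(row["best_reference"])


def select_candidates(table: pd.DataFrame, cutoff: float = 0.7) -> pd.DataFrame:
    """Retain rows with score >= cutoff (inclusive), ranked best-first.

    The cutoff comparison is inclusive; ties in score are broken by mol_id.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    if ((table["score"] < 0) | (table["score"] > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    kept = table[table["score"] >= cutoff]
    return kept.sort_values(["score", "mol_id"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)


def tanimoto_max(refs: Sequence[np.ndarray], fq: np.ndarray) -> float:
    """Baseline score: maximum Tanimoto similarity to any reference."""
    return max(tanimoto(r, fq) for r in refs)


def save_model(ts: TSModel, out_dir: str | Path) -> None:
    """Serialize a model bundle: manifest JSON plus a pickled model blob."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "vs_target": ts.vs_target,
        "scheme": ts.config.scheme,
        "levels": ts.training_meta.get("levels", []),
        "seed": ts.training_meta.get("seed"),
        "n_actives": len(ts.actives),
        "active_ids": ts.actives.ids(),
        "classifier": {"family": "random_forest",
                       "n_estimators": ts.config.n_estimators},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    with open(out / "model.pkl", "wb") as fh:
        pickle.dump(ts, fh)


def load_model(model_dir: str | Path) -> TSModel:
    model_dir = Path(model_dir)
    if not (model_dir / "manifest.json").exists():
        raise IOError(f"not a model bundle (missing manifest.json): {model_dir}")
    with open(model_dir / "model.pkl", "rb") as fh:
        return pickle.load(fh)
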