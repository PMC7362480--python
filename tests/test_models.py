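"""Pair featurization, level/ensemble training and target-specific scoring."""

import pickle

import numpy as np
import pytest

from ecbs.bench import (InteractionRecord, filter_actives, pr_curve,
                        RankedPredictions)
from ecbs.chemreg import MoleculeSet, molecule_from_bits
from ecbs.evoann import catalog_from_records
from ecbs.models import (ChemicalPair, LeakageError, TSConfig, TSModel,
                         build_training_pairs, pair_feature_matrix,
                         pair_features, score_chemicals, score_pair,
                         select_candidates, train_ensemble, train_level_model,
                         train_ts_model)
from ecbs.synth import SYNTH_SCHEME


# ---------------------------------------------------------------- features

class TestPairFeatures:
    def test_identity_pair_has_zero_xor_block(self):
        f = np.array([1, 0, 1, 1], dtype=np.uint8)
        feat = pair_features(f, f)
        assert np.array_equal(feat[4:], np.zeros(4))
        assert np.array_equal(feat[:4], f)

    def test_order_invariance(self, rng):
        fa = (rng.random(64) < 0.3).astype(np.uint8)
        fb = (rng.random(64) < 0.3).astype(np.uint8)
        assert np.array_equal(pair_features(fa, fb), pair_features(fb, fa))

    def test_feature_length_is_twice_fingerprint_length(self):
        assert len(pair_features(np.ones(67, np.uint8), np.ones(67, np.uint8))) == 134

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pair_features(np.ones(4, np.uint8), np.ones(5, np.uint8))


class TestChemicalPair:
    def test_unordered_storage(self):
        p = ChemicalPair("z", "a")
        assert (p.mol_a, p.mol_b) == ("a", "z")

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            ChemicalPair("a", "a")


# ------------------------------------------------------------ pair building

def _single_target_setup(n_actives=10, n_background=60):
    catalog = catalog_from_records([("T", "family", "F")], levels=("family",))
    interactions = [InteractionRecord(f"A{i}", "T", "Kd", 10.0)
                    for i in range(n_actives)]
    background = [f"B{i}" for i in range(n_background)]
    return interactions, catalog, background


class TestBuildTrainingPairs:
    def test_fourfold_negative_sampling(self):
        interactions, catalog, background = _single_target_setup()
        pairs = build_training_pairs(interactions, catalog, "family",
                                     background, neg_ratio=4, seed=0)
        neg = [p for p in pairs if not p.labels["family"]]
        pos = [p for p in pairs if p.labels["family"]]
        assert len(neg) == 40  # 10 actives x fourfold random partners
        assert len(pos) == 45  # C(10, 2)

    def test_same_seed_reproduces_pairs(self):
        interactions, catalog, background = _single_target_setup()
        a = build_training_pairs(interactions, catalog, "family", background, seed=5)
        b = build_training_pairs(interactions, catalog, "family", background, seed=5)
        assert [(p.key, p.labels) for p in a] == [(p.key, p.labels) for p in b]

    def test_zero_neg_ratio_rejected(self):
        interactions, catalog, background = _single_target_setup()
        with pytest.raises(ValueError, match="neg_ratio"):
            build_training_pairs(interactions, catalog, "family", background,
                                 neg_ratio=0)

    def test_small_background_names_shortfall(self):
        interactions, catalog, _ = _single_target_setup(n_background=0)
        with pytest.raises(ValueError, match="background pool too small"):
            build_training_pairs(interactions, catalog, "family", ["B0", "B1"],
                                 neg_ratio=4)


# ----------------------------------------------------- level/ensemble models

def _family_pairs(universe, seed=0):
    records = filter_actives(universe.interactions)
    background = universe.background_ids()
    return build_training_pairs(records, universe.catalog, "family",
                                background, neg_ratio=4, seed=seed,
                                max_positive_pairs=600)


def _eval_pr_auc(scorer, pairs, fingerprints):
    X = pair_feature_matrix(pairs, fingerprints)
    scores = scorer(X)
    rp = RankedPredictions([
        (f"p{i}", float(s), int(any(p.labels.values())))
        for i, (s, p) in enumerate(zip(scores, pairs))
    ])
    return pr_curve(rp).auc


def _three_way_split(universe, build_seed, split_seed):
    pairs = _family_pairs(universe, seed=build_seed)
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(pairs))
    n = len(pairs)
    train = [pairs[i] for i in order[: n // 2]]
    stack = [ChemicalPair(pairs[i].mol_a, pairs[i].mol_b, pairs[i].labels,
                          "test") for i in order[n // 2: 3 * n // 4]]
    hold = [pairs[i] for i in order[3 * n // 4:]]
    fps = universe.molecules.fingerprint_map(SYNTH_SCHEME)
    return train, stack, hold, fps


@pytest.fixture(scope="module")
def splits(small_universe):
    return _three_way_split(small_universe, build_seed=0, split_seed=0)


@pytest.fixture(scope="module")
def parts(small_universe):
    train, stack, hold, fps = _three_way_split(small_universe, build_seed=2,
                                               split_seed=1)
    lm = train_level_model("family", train, pair_feature_matrix(train, fps),
                           seed=1)
    return lm, train, stack, hold, fps


class TestLevelModel:
    def test_separable_pairs_reach_high_training_pr_auc(self, splits):
        train, _, _, fps = splits
        lm = train_level_model("family", train, pair_feature_matrix(train, fps),
                               seed=1)
        assert lm.training_meta["train_pr_auc"] > 0.95

    def test_permutation_control_scores_at_prevalence(self, splits):
        """With labels shuffled, held-out ranking collapses to prevalence."""
        train, _, hold, fps = splits
        rng = np.random.default_rng(3)
        y = [p.labels["family"] for p in train]
        shuffled = [ChemicalPair(p.mol_a, p.mol_b, {"family": bool(v)}, p.split)
                    for p, v in zip(train, rng.permutation(y))]
        lm = train_level_model("family", shuffled,
                               pair_feature_matrix(shuffled, fps), seed=1)
        auc = _eval_pr_auc(lm.score, hold, fps)
        prevalence = np.mean([any(p.labels.values()) for p in hold])
        assert abs(auc - prevalence) < 0.1

    def test_same_seed_gives_byte_identical_model(self, splits):
        train, _, _, fps = splits
        X = pair_feature_matrix(train, fps)
        a = train_level_model("family", train, X, seed=7)
        b = train_level_model("family", train, X, seed=7)
        assert pickle.dumps(a.classifier) == pickle.dumps(b.classifier)

    def test_single_class_input_rejected(self, splits):
        train, _, _, fps = splits
        pos_only = [p for p in train if p.labels["family"]][:10]
        with pytest.raises(ValueError, match="single class"):
            train_level_model("family", pos_only,
                              pair_feature_matrix(pos_only, fps))


class TestEnsemble:
    def test_stacking_preserves_level_performance(self, parts):
        lm, _, stack, hold, fps = parts
        ens = train_ensemble([lm], stack, fps, seed=0, scheme=SYNTH_SCHEME)
        level_auc = _eval_pr_auc(lm.score, hold, fps)
        ens_auc = _eval_pr_auc(ens.score_features, hold, fps)
        assert ens_auc >= level_auc - 0.02

    def test_stacker_is_robust_to_a_noise_level(self, parts):
        lm, train, stack, hold, fps = parts
        rng = np.random.default_rng(9)
        y = [p.labels["family"] for p in train]
        noise_pairs = [ChemicalPair(p.mol_a, p.mol_b, {"noise": bool(v)}, p.split)
                       for p, v in zip(train, rng.permutation(y))]
        noise_lm = train_level_model("noise", noise_pairs,
                                     pair_feature_matrix(noise_pairs, fps), seed=2)
        ens = train_ensemble([lm, noise_lm], stack, fps, seed=0,
                             scheme=SYNTH_SCHEME)
        informative_auc = _eval_pr_auc(lm.score, hold, fps)
        ens_auc = _eval_pr_auc(ens.score_features, hold, fps)
        assert ens_auc >= informative_auc - 0.05

    def test_zero_level_models_rejected(self, parts):
        _, _, stack, _, fps = parts
        with pytest.raises(ValueError, match="at least one level model"):
            train_ensemble([], stack, fps)

    def test_overlapping_splits_raise_leakage_error(self, parts):
        lm, train, _, _, fps = parts
        with pytest.raises(LeakageError):
            train_ensemble([lm], train, fps)

    def test_score_pair_symmetry_and_bounds(self, parts, rng):
        lm, _, stack, _, fps = parts
        ens = train_ensemble([lm], stack, fps, seed=0, scheme=SYNTH_SCHEME)
        for _ in range(10):
            fa = (rng.random(256) < 0.2).astype(np.uint8)
            fb = (rng.random(256) < 0.2).astype(np.uint8)
            s = score_pair(ens, fa, fb)
            assert 0.0 <= s <= 1.0
            assert s == score_pair(ens, fb, fa)

    def test_true_pairs_outscore_random_pairs(self, parts):
        lm, _, stack, hold, fps = parts
        ens = train_ensemble([lm], stack, fps, seed=0, scheme=SYNTH_SCHEME)
        X = pair_feature_matrix(hold, fps)
        scores = ens.score_features(X)
        y = np.array([any(p.labels.values()) for p in hold])
        assert scores[y].mean() > scores[~y].mean()


# --------------------------------------------------------- TS model scoring

class _LookupEnsemble:
    """Stub ensemble scoring a pair by the popcount of its AND block."""

    def __init__(self, table, length):
        self.table = table
        self.length = length

    def score_features(self, X):
        and_counts = X[:, : self.length].sum(axis=1)
        return np.array([self.table[int(c)] for c in and_counts], dtype=float)


def _stub_ts(table, refs, length=4):
    return TSModel(vs_target="T", ensemble=_LookupEnsemble(table, length),
                   actives=MoleculeSet(refs),
                   config=TSConfig(scheme=SYNTH_SCHEME))


class TestScoreChemicals:
    def test_maximum_score_rule(self):
        refs = [molecule_from_bits("r1", [1, 0, 0, 0]),
                molecule_from_bits("r2", [1, 1, 0, 0]),
                molecule_from_bits("r3", [1, 1, 1, 0])]
        ts = _stub_ts({1: 0.2, 2: 0.4, 3: 0.9}, refs)
        query = molecule_from_bits("q", [1, 1, 1, 1])
        out = score_chemicals(ts, [query])
        assert out.loc[0, "score"] == 0.9
        assert out.loc[0, "best_reference"] == "r3"

    def test_tie_goes_to_lexicographically_smallest_reference(self):
        refs = [molecule_from_bits("rB", [1, 1, 0, 0]),
                molecule_from_bits("rA", [1, 0, 1, 0])]
        ts = _stub_ts({2: 0.5}, refs)
        out = score_chemicals(ts, [molecule_from_bits("q", [1, 1, 1, 1])])
        assert out.loc[0, "best_reference"] == "rA"

    def test_single_reference_returns_its_pair_score(self):
        refs = [molecule_from_bits("r1", [1, 1, 0, 0])]
        ts = _stub_ts({2: 0.37}, refs)
        out = score_chemicals(ts, [molecule_from_bits("q", [1, 1, 1, 1])])
        assert out.loc[0, "score"] == 0.37

    def test_empty_reference_set_rejected(self):
        ts = _stub_ts({}, [molecule_from_bits("r1", [1, 0, 0, 0])])
        ts.actives = MoleculeSet([])
        with pytest.raises(ValueError, match="empty"):
            score_chemicals(ts, [molecule_from_bits("q", [1, 1, 1, 1])])

    def test_query_identical_to_reference_is_flagged_but_scored(self):
        ref = molecule_from_bits("r1", [1, 1, 0, 0])
        ts = _stub_ts({2: 0.8, 1: 0.1}, [ref])
        dup = molecule_from_bits("q_dup", [1, 1, 0, 0])
        out = score_chemicals(ts, [dup])
        assert bool(out.loc[0, "duplicate_of_reference"])
        assert out.loc[0, "score"] == 0.8

    def test_dedup_removes_duplicate_flags(self):
        """After canonical-key dedup against the references no query is
        flagged — the leakage audit the score table supports."""
        from ecbs.chemreg import deduplicate
        ref = molecule_from_bits("r1", [1, 1, 0, 0])
        ts = _stub_ts({2: 0.8, 1: 0.1}, [ref])
        queries = MoleculeSet([molecule_from_bits("q_dup", [1, 1, 0, 0]),
                               molecule_from_bits("q_new", [1, 0, 0, 0])])
        flagged = score_chemicals(ts, queries)
        cleaned = deduplicate(ts.actives, queries)
        after = score_chemicals(ts, cleaned)
        assert flagged["duplicate_of_reference"].sum() == 1
        assert after["duplicate_of_reference"].sum() == 0


class TestTrainTSModel:
    def test_reference_bookkeeping(self, small_universe):
        target = sorted(small_universe.truth.target_path)[0]
        n_actives = small_universe.config.actives_per_target
        model = train_ts_model(target, small_universe.interactions,
                               small_universe.catalog, small_universe.molecules,
                               config=TSConfig(scheme=SYNTH_SCHEME), seed=0)
        assert model.vs_target == target
        assert len(model.actives) == n_actives

    def test_few_actives_emits_advisory_warning(self, small_universe):
        target = sorted(small_universe.truth.target_path)[0]
        cfg = TSConfig(scheme=SYNTH_SCHEME, warn_threshold=50)
        with pytest.warns(UserWarning, match="advisory"):
            train_ts_model(target, small_universe.interactions,
                           small_universe.catalog, small_universe.molecules,
                           config=cfg, seed=0)

    def test_unknown_target_rejected(self, small_universe):
        with pytest.raises(KeyError):
            train_ts_model("NOPE", small_universe.interactions,
                           small_universe.catalog, small_universe.molecules)

    def test_score_table_is_deterministic(self, small_universe):
        target = sorted(small_universe.truth.target_path)[0]
        queries = [m for m in small_universe.molecules
                   if m.mol_id.startswith("BG")][:20]
        tables = []
        for _ in range(2):
            model = train_ts_model(target, small_universe.interactions,
                                   small_universe.catalog,
                                   small_universe.molecules,
                                   config=TSConfig(scheme=SYNTH_SCHEME), seed=11)
            tables.append(score_chemicals(model, queries))
        assert tables[0].equals(tables[1])


class TestSelectCandidates:
    def _table(self, scores):
        import pandas as pd
        return pd.DataFrame({
            "mol_id": [f"m{i}" for i in range(len(scores))],
            "score": scores,
            "best_reference": ["r"] * len(scores),
        })

    def test_inclusive_cutoff(self):
        out = select_candidates(self._table([0.69, 0.70, 0.71]), cutoff=0.7)
        assert sorted(out["score"]) == [0.70, 0.71]

    def test_cutoff_zero_keeps_everything(self):
        assert len(select_candidates(self._table([0.1, 0.5, 0.9]), cutoff=0.0)) == 3

    def test_unreachable_cutoff_gives_empty_table(self):
        out = select_candidates(self._table([0.2, 0.8]), cutoff=1.0)
        assert len(out) == 0

    def test_cutoff_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            select_candidates(self._table([0.5]), cutoff=1.5)

    def test_sorted_descending_with_id_tiebreak(self):
        import pandas as pd
        table = pd.DataFrame({"mol_id": ["b", "a", "c"],
                              "score": [0.9, 0.9, 0.95],
                              "best_reference": ["r"] * 3})
        out = select_candidates(table, cutoff=0.5)
        assert out["mol_id"].tolist() == ["c", "a", "b"]
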