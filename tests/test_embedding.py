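"""Scoring function, negative sampling, training, and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsds.corpus import FieldType
from dsds.embedding import (
    ComplexEmbeddings,
    TrainConfig,
    load_checkpoint,
    rank_candidates,
    sample_negatives,
    save_checkpoint,
    score_triple,
    train_model,
)
from dsds.kg import KnowledgeGraph, Triple


def _emb(entities, relations):
    return ComplexEmbeddings(np.array(entities), np.array(relations))


def naive_score(h, l, t, emb):
    """Independent per-component complex-arithmetic oracle."""
    total = 0.0
    for k in range(emb.dim):
        eh = complex(emb.entity_table[h, k])
        el = complex(emb.relation_table[l, k])
        et = complex(emb.entity_table[t, k])
        total += (eh * el * et.conjugate()).real
    return total


class TestScoreTriple:
    def test_zero_embeddings(self):
        emb = _emb(np.zeros((2, 3), complex), np.zeros((1, 3), complex))
        assert score_triple(0, 0, 1, emb) == 0.0

    def test_hand_computed_d1(self):
        # Re((1+i) * i * conj(1-i)) = Re((1+i) * i * (1+i)) = Re(2i*i) = -2
        emb = _emb([[1 + 1j], [1 - 1j]], [[0 + 1j]])
        assert score_triple(0, 0, 1, emb) == pytest.approx(-2.0)

    def test_out_of_range_ids(self, random_embeddings):
        with pytest.raises(IndexError):
            score_triple(99, 0, 0, random_embeddings)
        with pytest.raises(IndexError):
            score_triple(0, 99, 0, random_embeddings)

    def test_matches_naive_oracle_100_instances(self):
        rng = np.random.default_rng(0)
        emb = ComplexEmbeddings(
            rng.normal(size=(20, 6)) + 1j * rng.normal(size=(20, 6)),
            rng.normal(size=(4, 6)) + 1j * rng.normal(size=(4, 6)),
        )
        for _ in range(100):
            h, t = rng.integers(20, size=2)
            l = rng.integers(4)
            fast = score_triple(int(h), int(l), int(t), emb)
            assert fast == pytest.approx(naive_score(h, l, t, emb), abs=1e-9)

    def test_real_relation_symmetric_100_trials(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            ents = rng.normal(size=(2, 5)) + 1j * rng.normal(size=(2, 5))
            rels = rng.normal(size=(1, 5)) + 0j  # purely real
            emb = ComplexEmbeddings(ents, rels)
            assert score_triple(0, 0, 1, emb) == pytest.approx(
                score_triple(1, 0, 0, emb), abs=1e-9
            )

    def test_imaginary_relation_antisymmetric_100_trials(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            ents = rng.normal(size=(2, 5)) + 1j * rng.normal(size=(2, 5))
            rels = 1j * rng.normal(size=(1, 5))  # purely imaginary
            emb = ComplexEmbeddings(ents, rels)
            assert score_triple(0, 0, 1, emb) == pytest.approx(
                -score_triple(1, 0, 0, emb), abs=1e-9
            )

    def test_non_finite_embeddings_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            _emb([[np.inf + 0j]], [[0j]])


def _kg_with_entities(n_symptoms, n_syndromes):
    kg = KnowledgeGraph()
    rel = kg.add_relation("inspection-syndrome", "symptom-syndrome", FieldType.INSPECTION)
    syms = [kg.add_entity(f"sym{i}", FieldType.INSPECTION) for i in range(n_symptoms)]
    syns = [kg.add_entity(f"S{i}", FieldType.SYNDROME) for i in range(n_syndromes)]
    return kg, rel, syms, syns


class TestSampleNegatives:
    def test_forced_outcome_two_entity_vocab(self):
        kg, rel, syms, syns = _kg_with_entities(1, 2)
        kg.add_triple(syms[0], rel, syns[0])
        negs = sample_negatives(kg.triples[0], kg, 3, "tail", rng=0, filtered=True)
        assert all(n.t == syns[1] for n in negs)

    def test_filtered_corruptions_not_in_kg(self):
        kg, rel, syms, syns = _kg_with_entities(5, 100)
        for i in range(5):
            kg.add_triple(syms[i], rel, syns[i])
        negs = sample_negatives(kg.triples[0], kg, 10, "tail", rng=1, filtered=True)
        assert len(negs) == 10
        assert all(n not in kg for n in negs)

    def test_same_seed_identical(self):
        kg, rel, syms, syns = _kg_with_entities(2, 50)
        kg.add_triple(syms[0], rel, syns[0])
        a = sample_negatives(kg.triples[0], kg, 20, "tail", rng=7)
        b = sample_negatives(kg.triples[0], kg, 20, "tail", rng=7)
        assert a == b

    def test_tail_mode_type_aware(self):
        kg, rel, syms, syns = _kg_with_entities(5, 5)
        kg.add_triple(syms[0], rel, syns[0])
        negs = sample_negatives(kg.triples[0], kg, 30, "tail", rng=3)
        for n in negs:
            assert kg.entities[n.t].etype is FieldType.SYNDROME
            assert n.t != syns[0]

    def test_head_mode_preserves_tail(self):
        kg, rel, syms, syns = _kg_with_entities(5, 5)
        kg.add_triple(syms[0], rel, syns[0])
        negs = sample_negatives(kg.triples[0], kg, 10, "head", rng=3)
        for n in negs:
            assert n.t == syns[0] and n.h != syms[0]
            assert kg.entities[n.h].etype is FieldType.INSPECTION

    def test_both_mode(self):
        kg, rel, syms, syns = _kg_with_entities(5, 5)
        kg.add_triple(syms[0], rel, syns[0])
        negs = sample_negatives(kg.triples[0], kg, 40, "both", rng=3)
        assert any(n.t != syns[0] for n in negs)
        assert any(n.h != syms[0] for n in negs)

    def test_no_valid_corruption(self):
        kg, rel, syms, syns = _kg_with_entities(1, 1)
        kg.add_triple(syms[0], rel, syns[0])
        with pytest.raises(ValueError, match="no valid corruption"):
            sample_negatives(kg.triples[0], kg, 1, "tail", rng=0)

    def test_bad_count(self, toy_pair_kg):
        with pytest.raises(ValueError):
            sample_negatives(toy_pair_kg.triples[0], toy_pair_kg, 0, "tail")

    def test_bad_mode(self, toy_pair_kg):
        with pytest.raises(ValueError, match="mode"):
            sample_negatives(toy_pair_kg.triples[0], toy_pair_kg, 1, "sideways")


class TestTrainModel:
    def test_positives_beat_filtered_corruptions(self, trained_toy):
        kg, emb = trained_toy
        for trip in kg.triples:
            pos = score_triple(trip.h, trip.l, trip.t, emb)
            for cand in kg.syndrome_ids:
                if Triple(trip.h, trip.l, cand) in kg:
                    continue
                assert pos > score_triple(trip.h, trip.l, cand, emb)

    def test_positive_mean_above_corruption_mean(self, trained_toy):
        kg, emb = trained_toy
        pos = [score_triple(t.h, t.l, t.t, emb) for t in kg.triples]
        neg = [
            score_triple(t.h, t.l, c, emb)
            for t in kg.triples
            for c in kg.syndrome_ids
            if c != t.t
        ]
        assert np.mean(pos) > 0 > np.mean(neg)

    def test_zero_epochs_returns_seeded_init(self, toy_pair_kg):
        cfg = TrainConfig(dim=4, epochs=0, seed=9)
        a = train_model(toy_pair_kg, cfg)
        b = train_model(toy_pair_kg, cfg)
        np.testing.assert_array_equal(a.entity_table, b.entity_table)
        assert a.loss_history == []

    def test_bit_identical_given_seed(self, toy_pair_kg):
        cfg = TrainConfig(dim=8, epochs=30, seed=5, batch_size=4)
        a = train_model(toy_pair_kg, cfg)
        b = train_model(toy_pair_kg, cfg)
        np.testing.assert_array_equal(a.entity_table, b.entity_table)
        np.testing.assert_array_equal(a.relation_table, b.relation_table)
        assert a.loss_history == b.loss_history

    def test_loss_mostly_non_increasing(self, toy_pair_kg):
        cfg = TrainConfig(dim=8, epochs=100, learning_rate=0.02, seed=1, batch_size=0,
                          negatives=2)
        emb = train_model(toy_pair_kg, cfg)
        losses = np.array(emb.loss_history)
        increases = int((np.diff(losses) > 1e-12).sum())
        assert increases <= 0.05 * len(losses)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_model(KnowledgeGraph(), TrainConfig(dim=2, epochs=1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(dim=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)
        with pytest.raises(ValueError):
            TrainConfig(negatives=0)


class TestRankCandidates:
    def test_single_candidate(self, random_embeddings):
        out = rank_candidates(0, 0, [3], random_embeddings)
        assert len(out) == 1 and out[0][0] == 3

    def test_matches_brute_force_oracle(self, random_embeddings):
        rng = np.random.default_rng(3)
        cands = list(rng.choice(12, size=10, replace=False))
        got = rank_candidates(1, 2, cands, random_embeddings)
        oracle = sorted(
            ((c, score_triple(1, 2, int(c), random_embeddings)) for c in cands),
            key=lambda cs: (-cs[1], cs[0]),
        )
        assert [(c, pytest.approx(s)) for c, s in oracle] == got

    def test_deterministic_tie_break(self):
        emb = _emb(np.zeros((5, 2), complex), np.zeros((1, 2), complex))
        out = rank_candidates(0, 0, [4, 2, 3], emb)
        assert [c for c, _ in out] == [2, 3, 4]  # all scores 0 -> id order

    def test_perturbing_toward_query_never_worsens_rank(self, random_embeddings):
        emb = random_embeddings
        cands = list(range(2, 10))
        before = [c for c, _ in rank_candidates(0, 1, cands, emb)]
        target = before[-1]
        # move the worst candidate toward the query product h*l (the score
        # maximiser direction) and check it only climbs
        boost = np.conj(emb.entity_table[0] * emb.relation_table[1])
        for step in (0.5, 2.0, 10.0):
            ents = emb.entity_table.copy()
            ents[target] += step * np.conj(boost)
            after = [c for c, _ in rank_candidates(
                0, 1, cands, ComplexEmbeddings(ents, emb.relation_table))]
            assert after.index(target) <= before.index(target)
            before = after

    def test_empty_candidates(self, random_embeddings):
        with pytest.raises(ValueError):
            rank_candidates(0, 0, [], random_embeddings)


class TestCheckpoint:
    def test_round_trip(self, trained_toy, tmp_path):
        _, emb = trained_toy
        path = save_checkpoint(emb, tmp_path / "ck.npz", vocab_hash="abc123")
        back, vh = load_checkpoint(path)
        np.testing.assert_array_equal(back.entity_table, emb.entity_table)
        np.testing.assert_array_equal(back.relation_table, emb.relation_table)
        assert vh == "abc123"
        assert back.config == emb.config
        assert back.loss_history == emb.loss_history
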