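import numpy as np
import pytest

from dsds.corpus import EMRecord, FieldType
from dsds.embedding import ComplexEmbeddings, TrainConfig, train_model
from dsds.kg import KnowledgeGraph, build_kg


@pytest.fixture
def sample_records() -> list[EMRecord]:
    return [
        EMRecord(
            record_id="r1",
            fields={
                FieldType.PULSE_TAKING: "two-inch floating pulse",
                FieldType.TONGUE_INSPECTION: "white and thin tongue fur",
            },
            syndrome="wind-cold",
        ),
        EMRecord(
            record_id="r2",
            fields={
                FieldType.PULSE_TAKING: "stringlike pulse，two-inch floating pulse",
                FieldType.INSPECTION: "cough",
            },
            syndrome="phlegm-heat",
        ),
        EMRecord(
            record_id="r3",
            fields={
                FieldType.TONGUE_INSPECTION: "reddish tongue texture",
                FieldType.NURSING_PRECAUTIONS: "rest，drink water",
            },
            syndrome="wind-cold",
        ),
        EMRecord(
            record_id="r4",
            fields={FieldType.LISTENING_AND_SMELLING: "hoarse voice"},
            syndrome="phlegm-heat",
        ),
        EMRecord(
            record_id="r5",
            fields={FieldType.BODY_SURFACE_EXAMINATION: "swollen tonsil"},
            syndrome="wind-cold",
        ),
    ]


@pytest.fixture
def sample_kg(sample_records) -> KnowledgeGraph:
    return build_kg(sample_records)


@pytest.fixture
def toy_pair_kg() -> KnowledgeGraph:
    """Three deterministic symptom->syndrome pairs, one relation."""
    kg = KnowledgeGraph()
    rel = kg.add_relation("pulse taking-syndrome", "symptom-syndrome", FieldType.PULSE_TAKING)
    for i in range(3):
        sym = kg.add_entity(f"sym{i}", FieldType.PULSE_TAKING)
        syn = kg.add_entity(f"S{i}", FieldType.SYNDROME)
        kg.add_triple(sym, rel, syn)
    return kg


@pytest.fixture(scope="session")
def trained_toy():
    """A small trained model shared across tests that only need *a* model."""
    kg = KnowledgeGraph()
    rel = kg.add_relation("pulse taking-syndrome", "symptom-syndrome", FieldType.PULSE_TAKING)
    for i in range(3):
        sym = kg.add_entity(f"sym{i}", FieldType.PULSE_TAKING)
        syn = kg.add_entity(f"S{i}", FieldType.SYNDROME)
        kg.add_triple(sym, rel, syn)
    cfg = TrainConfig(
        dim=8, epochs=200, learning_rate=0.1, negatives=2, batch_size=0, seed=1,
        resample_negatives=True,
    )
    return kg, train_model(kg, cfg)


@pytest.fixture
def random_embeddings() -> ComplexEmbeddings:
    rng = np.random.default_rng(42)
    ent = rng.normal(size=(12, 4)) + 1j * rng.normal(size=(12, 4))
    rel = rng.normal(size=(3, 4)) + 1j * rng.normal(size=(3, 4))
    return ComplexEmbeddings(ent, rel)
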