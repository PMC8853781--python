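"""Knowledge-graph construction from clinical records, plus triple file I/O.

For every record, each segmented token ``s`` of diagnostic field type ``t``
emits two triples::

    (method_node(t), "performance of {t}", s)
    (s,             "{t}-syndrome",        syndrome)

Method nodes are shared across records (one per field type) so the graph
stays connected.  Nursing-precaution triples are kept in the graph for
richness but flagged so prediction can exclude them.  Entity identity is
the pair (name, field type): the same string under two field types is two
distinct entities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import (
    DEFAULT_PUNCTUATION,
    DIAGNOSTIC_FIELDS,
    EMRecord,
    FieldType,
    segment_field,
)

__all__ = [
    "Entity",
    "Relation",
    "Triple",
    "KnowledgeGraph",
    "EntityStats",
    "TypeStats",
    "build_kg",
    "repetition_percentage",
    "entity_statistics",
    "export_triples",
    "import_triples",
    "performance_relation",
    "syndrome_relation",
]

_METHOD_PREFIX = "[method] "


def performance_relation(ft: FieldType) -> str:
    return f"performance of {ft.value}"


def syndrome_relation(ft: FieldType) -> str:
    return f"{ft.value}-syndrome"


@dataclass(frozen=True)
class Entity:
    """A typed graph node; identity is the (name, etype) pair."""

    name: str
    etype: FieldType

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("entity name must be non-empty")


@dataclass(frozen=True)
class Relation:
    name: str
    kind: str  # "method-performance" | "symptom-syndrome"
    field_type: FieldType

    @property
    def excluded_from_diagnosis(self) -> bool:
        """Nursing precautions stay in the graph but never drive prediction."""
        return self.field_type is FieldType.NURSING_PRECAUTIONS


@dataclass(frozen=True)
class Triple:
    h: int
    l: int
    t: int


class KnowledgeGraph:
    """Typed entity vocabulary, relation vocabulary, deduplicated triples."""

    def __init__(self) -> None:
        self.entities: list[Entity] = []
        self.relations: list[Relation] = []
        self._entity_ids: dict[Entity, int] = {}
        self._relation_ids: dict[str, int] = {}
        self.triples: list[Triple] = []
        self._triple_set: set[Triple] = set()

    # -- vocabulary ------------------------------------------------------
    def add_entity(self, name: str, etype: FieldType) -> int:
        ent = Entity(name, FieldType(etype))
        eid = self._entity_ids.get(ent)
        if eid is None:
            eid = len(self.entities)
            self.entities.append(ent)
            self._entity_ids[ent] = eid
        return eid

    def add_relation(self, name: str, kind: str, field_type: FieldType) -> int:
        rid = self._relation_ids.get(name)
        if rid is None:
            rid = len(self.relations)
            self.relations.append(Relation(name, kind, FieldType(field_type)))
            self._relation_ids[name] = rid
        return rid

    def entity_id(self, name: str, etype: FieldType) -> int | None:
        return self._entity_ids.get(Entity(name, FieldType(etype)))

    def relation_id(self, name: str) -> int | None:
        return self._relation_ids.get(name)

    # -- triples ---------------------------------------------------------
    def add_triple(self, h: int, l: int, t: int) -> bool:
        """Add a triple; returns False if it was already present."""
        n_e, n_r = len(self.entities), len(self.relations)
        if not (0 <= h < n_e and 0 <= t < n_e):
            raise IndexError(f"entity id out of range in triple ({h},{l},{t})")
        if not 0 <= l < n_r:
            raise IndexError(f"relation id {l} out of range")
        trip = Triple(h, l, t)
        if trip in self._triple_set:
            return False
        self._triple_set.add(trip)
        self.triples.append(trip)
        return True

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triple_set

    def __len__(self) -> int:
        return len(self.triples)

    # -- typed views -----------------------------------------------------
    def entity_ids_of_type(self, etype: FieldType) -> list[int]:
        etype = FieldType(etype)
        return [i for i, e in enumerate(self.entities) if e.etype is etype]

    @property
    def syndrome_ids(self) -> list[int]:
        return self.entity_ids_of_type(FieldType.SYNDROME)

    def tail_candidates(self, rid: int) -> list[int]:
        """Legal tail entity ids for a relation, by the schema's typing."""
        rel = self.relations[rid]
        if rel.kind == "symptom-syndrome":
            return self.syndrome_ids
        return [
            i
            for i in self.entity_ids_of_type(rel.field_type)
            if not self.entities[i].name.startswith(_METHOD_PREFIX)
        ]


def build_kg(
    records: Sequence[EMRecord],
    *,
    include_nursing: bool = True,
    punctuation: str = DEFAULT_PUNCTUATION,
) -> KnowledgeGraph:
    """Construct the graph from labelled records.

    Raises ``ValueError`` on an empty corpus or any unlabelled record.
    """
    if not records:
        raise ValueError("cannot build a knowledge graph from an empty corpus")
    kg = KnowledgeGraph()
    for rec in records:
        if not rec.is_labelled:
            raise ValueError(f"record {rec.record_id!r} lacks a syndrome label")
    for rec in records:
        syn_id = kg.add_entity(rec.syndrome, FieldType.SYNDROME)
        for ft in DIAGNOSTIC_FIELDS:
            if ft is FieldType.NURSING_PRECAUTIONS and not include_nursing:
                continue
            tokens = segment_field(rec.fields.get(ft, ""), punctuation)
            if not tokens:
                continue
            method_id = kg.add_entity(_METHOD_PREFIX + ft.value, ft)
            perf_rid = kg.add_relation(performance_relation(ft), "method-performance", ft)
            syn_rid = kg.add_relation(syndrome_relation(ft), "symptom-syndrome", ft)
            for tok in tokens:
                tok_id = kg.add_entity(tok, ft)
                kg.add_triple(method_id, perf_rid, tok_id)
                kg.add_triple(tok_id, syn_rid, syn_id)
    return kg


# --------------------------------------------------------------------------
# Corpus statistics
# --------------------------------------------------------------------------


def repetition_percentage(participle_count: int, dedup_count: int) -> float:
    """``100 * (1 - dedup/participle)`` rounded half-up to one decimal."""
    if participle_count <= 0:
        raise ValueError("participle_count must be positive")
    if not 0 < dedup_count <= participle_count:
        raise ValueError("need 0 < dedup_count <= participle_count")
    pct = 100 * (1 - Decimal(dedup_count) / Decimal(participle_count))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class TypeStats:
    original: int = 0  # raw non-empty field instances
    participle: int = 0  # token occurrences after segmentation
    dedup: int = 0  # unique token strings
    repetition: float = 0.0


@dataclass
class EntityStats:
    """Per-field-type redundancy statistics for a corpus."""

    per_type: dict[FieldType, TypeStats] = field(default_factory=dict)

    @property
    def total_original(self) -> int:
        return sum(s.original for s in self.per_type.values())

    @property
    def total_participle(self) -> int:
        return sum(s.participle for s in self.per_type.values())

    @property
    def total_dedup(self) -> int:
        return sum(s.dedup for s in self.per_type.values())

    @property
    def average_repetition(self) -> float:
        """Arithmetic mean of the per-type percentages, to one decimal."""
        pcts = [s.repetition for s in self.per_type.values()]
        if not pcts:
            return 0.0
        mean = Decimal(str(sum(Decimal(str(p)) for p in pcts))) / len(pcts)
        return float(mean.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def entity_statistics(
    records: Sequence[EMRecord],
    punctuation: str = DEFAULT_PUNCTUATION,
) -> EntityStats:
    """Original / segmented / deduplicated counts per field type.

    Syndrome labels are never segmented: their participle count equals the
    number of labelled records and their unique count is the number of
    distinct labels.
    """
    stats = EntityStats()
    uniq: dict[FieldType, set[str]] = {ft: set() for ft in FieldType}
    for ft in FieldType:
        stats.per_type[ft] = TypeStats()
    for rec in records:
        for ft in DIAGNOSTIC_FIELDS:
            raw = rec.fields.get(ft, "")
            ts = stats.per_type[ft]
            if raw.strip():
                ts.original += 1
            toks = segment_field(raw, punctuation)
            ts.participle += len(toks)
            uniq[ft].update(toks)
        if rec.is_labelled:
            ss = stats.per_type[FieldType.SYNDROME]
            ss.original += 1
            ss.participle += 1
            uniq[FieldType.SYNDROME].add(rec.syndrome)
    for ft in FieldType:
        ts = stats.per_type[ft]
        ts.dedup = len(uniq[ft])
        if ts.participle > 0 and ts.dedup > 0:
            ts.repetition = repetition_percentage(ts.participle, ts.dedup)
    return stats


# --------------------------------------------------------------------------
# Triple file I/O: triples.tsv + entities.tsv + relations.tsv sidecars
# --------------------------------------------------------------------------

_TRIPLES = "triples.tsv"
_ENTITIES = "entities.tsv"
_RELATIONS = "relations.tsv"


def export_triples(kg: KnowledgeGraph, out_dir: str | Path) -> Path:
    """Write the graph as three tab-separated files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / _ENTITIES).open("w", encoding="utf-8") as fh:
        fh.write("id\tname\tetype\n")
        for i, ent in enumerate(kg.entities):
            fh.write(f"{i}\t{ent.name}\t{ent.etype.value}\n")
    with (out / _RELATIONS).open("w", encoding="utf-8") as fh:
        fh.write("id\tname\tkind\tfield_type\n")
        for i, rel in enumerate(kg.relations):
            fh.write(f"{i}\t{rel.name}\t{rel.kind}\t{rel.field_type.value}\n")
    with (out / _TRIPLES).open("w", encoding="utf-8") as fh:
        fh.write("head\trelation\ttail\n")
        for trip in kg.triples:
            h = kg.entities[trip.h]
            r = kg.relations[trip.l]
            t = kg.entities[trip.t]
            fh.write(f"{h.name}\t{r.name}\t{t.name}\n")
    return out


def import_triples(in_dir: str | Path) -> KnowledgeGraph:
    """Inverse of :func:`export_triples`; validates every reference."""
    src = Path(in_dir)
    kg = KnowledgeGraph()
    by_name: dict[str, list[int]] = {}
    with (src / _ENTITIES).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != "id\tname\tetype":
            raise ValueError(f"{src / _ENTITIES}: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                _, name, etype = line.split("\t")
                eid = kg.add_entity(name, FieldType(etype))
            except ValueError as exc:
                raise ValueError(f"{src / _ENTITIES}:{lineno}: {exc}") from exc
            by_name.setdefault(name, []).append(eid)
    with (src / _RELATIONS).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != "id\tname\tkind\tfield_type":
            raise ValueError(f"{src / _RELATIONS}: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                _, name, kind, ft = line.split("\t")
                kg.add_relation(name, kind, FieldType(ft))
            except ValueError as exc:
                raise ValueError(f"{src / _RELATIONS}:{lineno}: {exc}") from exc
    with (src / _TRIPLES).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != "head\trelation\ttail":
            raise ValueError(f"{src / _TRIPLES}: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{src / _TRIPLES}:{lineno}: expected 3 columns")
            hname, rname, tname = parts
            rid = kg.relation_id(rname)
            if rid is None:
                raise ValueError(f"{src / _TRIPLES}:{lineno}: unknown relation {rname!r}")
            rel = kg.relations[rid]
            hid = _resolve(kg, by_name, hname, rel, slot="head")
            tid = _resolve(kg, by_name, tname, rel, slot="tail")
            if hid is None or tid is None:
                raise ValueError(
                    f"{src / _TRIPLES}:{lineno}: undeclared entity in "
                    f"({hname!r}, {rname!r}, {tname!r})"
                )
            kg.add_triple(hid, rid, tid)
    return kg


def _resolve(
    kg: KnowledgeGraph,
    by_name: dict[str, list[int]],
    name: str,
    rel: Relation,
    *,
    slot: str,
) -> int | None:
    # Schema typing makes the lookup unambiguous: a symptom-syndrome tail is
    # a syndrome entity; every other slot carries the relation's field type.
    if rel.kind == "symptom-syndrome" and slot == "tail":
        want = FieldType.SYNDROME
    else:
        want = rel.field_type
    eid = kg.entity_id(name, want)
    if eid is not None:
        return eid
    candidates = by_name.get(name, [])
    return candidates[0] if len(candidates) == 1 else None
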