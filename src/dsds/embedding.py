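"""Complex-valued knowledge-graph embeddings: scoring, sampling, training.

Entities and relations live in C^d; the score of a triple (h, l, t) is the
real part of the Hermitian three-way product

    phi(h, l, t) = Re sum_k  e_h[k] * e_l[k] * conj(e_t[k])

which can express both symmetric relations (real relation vector) and
antisymmetric ones (imaginary relation vector).  Training minimises a
pointwise logistic loss over positive triples (label +1) and sampled
corruptions (label -1) with L2 regularisation, by plain full-batch SGD.
Corruptions are tail-only by default and type-aware: a tail is replaced
only by entities that are legal tails of the triple's relation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .kg import KnowledgeGraph, Triple

__all__ = [
    "TrainConfig",
    "ComplexEmbeddings",
    "score_triple",
    "score_triples",
    "sample_negatives",
    "train_model",
    "rank_candidates",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Hyperparameters; all overridable, none dictated by published values."""

    dim: int = 100
    epochs: int = 200
    learning_rate: float = 0.05
    negatives: int = 20
    reg: float = 1e-3
    batch_size: int = 512  # 0 => full batch
    seed: int = 0
    init_sigma: float = 0.1
    resample_negatives: bool = False  # True => fresh corruptions every epoch

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("dim must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if self.reg < 0:
            raise ValueError("reg must be >= 0")


@dataclass
class ComplexEmbeddings:
    """Per-entity and per-relation complex vectors of dimension ``dim``.

    Tables are complex128 arrays indexed by vocabulary id.
    """

    entity_table: np.ndarray
    relation_table: np.ndarray
    config: TrainConfig | None = None
    loss_history: list[float] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.entity_table.shape[1]

    @property
    def n_entities(self) -> int:
        return self.entity_table.shape[0]

    @property
    def n_relations(self) -> int:
        return self.relation_table.shape[0]

    def __post_init__(self) -> None:
        self.entity_table = np.asarray(self.entity_table, dtype=np.complex128)
        self.relation_table = np.asarray(self.relation_table, dtype=np.complex128)
        if self.entity_table.ndim != 2 or self.relation_table.ndim != 2:
            raise ValueError("embedding tables must be 2-D")
        if self.entity_table.shape[1] != self.relation_table.shape[1]:
            raise ValueError("entity and relation dimensions must agree")
        if not (np.isfinite(self.entity_table).all() and np.isfinite(self.relation_table).all()):
            raise ValueError("embeddings must be finite")


def _check_ids(emb: ComplexEmbeddings, h: int, l: int, t: int) -> None:
    if not (0 <= h < emb.n_entities and 0 <= t < emb.n_entities):
        raise IndexError(f"entity id out of range: ({h}, {t})")
    if not 0 <= l < emb.n_relations:
        raise IndexError(f"relation id out of range: {l}")


def score_triple(h: int, l: int, t: int, emb: ComplexEmbeddings) -> float:
    """Real part of the Hermitian product over the triple's vectors."""
    _check_ids(emb, h, l, t)
    eh = emb.entity_table[h]
    el = emb.relation_table[l]
    et = emb.entity_table[t]
    return float(np.real(np.sum(eh * el * np.conj(et))))


def score_triples(
    h: np.ndarray, l: np.ndarray, t: np.ndarray, emb: ComplexEmbeddings
) -> np.ndarray:
    """Vectorised scoring for parallel arrays of ids."""
    eh = emb.entity_table[h]
    el = emb.relation_table[l]
    et = emb.entity_table[t]
    return np.real(np.sum(eh * el * np.conj(et), axis=-1))


def sample_negatives(
    triple: Triple,
    kg: KnowledgeGraph,
    count: int,
    mode: str = "tail",
    rng: np.random.Generator | int | None = None,
    *,
    filtered: bool = False,
) -> list[Triple]:
    """Draw ``count`` corrupted variants of ``triple``.

    The chosen slot is replaced by an entity drawn uniformly (with
    replacement) from the type-legal candidates, never the original entity.
    Under ``filtered`` mode no corruption may itself be a known triple of
    ``kg``.  ``mode`` is one of ``tail``, ``head``, ``both``; in ``both``
    mode the slot is chosen uniformly per corruption.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if mode not in ("tail", "head", "both"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def pool(slot: str) -> list[int]:
        if slot == "tail":
            cands = kg.tail_candidates(triple.l)
            keep = triple.t
        else:
            etype = kg.entities[triple.h].etype
            cands = kg.entity_ids_of_type(etype)
            keep = triple.h
        cands = [c for c in cands if c != keep]
        if filtered:
            if slot == "tail":
                cands = [c for c in cands if Triple(triple.h, triple.l, c) not in kg]
            else:
                cands = [c for c in cands if Triple(c, triple.l, triple.t) not in kg]
        return cands

    pools = {s: pool(s) for s in (("tail", "head") if mode == "both" else (mode,))}
    slots = list(pools)
    if all(not p for p in pools.values()):
        raise ValueError(f"no valid corruption exists for triple {triple} in mode {mode!r}")

    out: list[Triple] = []
    for _ in range(count):
        slot = slots[int(rng.integers(len(slots)))] if len(slots) > 1 else slots[0]
        if not pools[slot]:  # one side exhausted under filtering
            slot = next(s for s in slots if pools[s])
        repl = pools[slot][int(rng.integers(len(pools[slot])))]
        if slot == "tail":
            out.append(Triple(triple.h, triple.l, repl))
        else:
            out.append(Triple(repl, triple.l, triple.t))
    return out


def _init_tables(
    n_entities: int, n_relations: int, cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    shape_e = (n_entities, cfg.dim)
    shape_r = (n_relations, cfg.dim)
    ent = rng.normal(0.0, cfg.init_sigma, shape_e) + 1j * rng.normal(0.0, cfg.init_sigma, shape_e)
    rel = rng.normal(0.0, cfg.init_sigma, shape_r) + 1j * rng.normal(0.0, cfg.init_sigma, shape_r)
    return ent, rel


def train_model(kg: KnowledgeGraph, config: TrainConfig | None = None) -> ComplexEmbeddings:
    """Fit embeddings to the graph's triples.

    Each epoch resamples type-aware tail corruptions (``config.negatives``
    per positive), computes the logistic loss over positives and negatives,
    and applies one (mini)batched SGD step per batch.  Raises ``RuntimeError``
    naming the epoch if the loss turns non-finite.
    """
    if len(kg) == 0:
        raise ValueError("cannot train on an empty knowledge graph")
    cfg = config or TrainConfig()
    ent, rel = _init_tables(len(kg.entities), len(kg.relations), cfg)
    emb = ComplexEmbeddings(ent, rel, config=cfg)
    if cfg.epochs == 0:
        return emb

    rng = np.random.default_rng(cfg.seed + 1)
    pos_h = np.array([tr.h for tr in kg.triples], dtype=np.int64)
    pos_l = np.array([tr.l for tr in kg.triples], dtype=np.int64)
    pos_t = np.array([tr.t for tr in kg.triples], dtype=np.int64)
    n_pos = len(pos_h)

    # Per-relation legal tail pools for type-aware corruption.
    tail_pools = {rid: np.array(kg.tail_candidates(rid), dtype=np.int64)
                  for rid in range(len(kg.relations))}
    for rid, pool in tail_pools.items():
        if pool.size == 0:
            tail_pools[rid] = np.arange(len(kg.entities), dtype=np.int64)

    neg = cfg.negatives

    def draw_corruptions() -> np.ndarray:
        # corrupt tails within the relation's legal tail type
        neg_t = np.empty(n_pos * neg, dtype=np.int64)
        for rid, pool in tail_pools.items():
            mask = np.repeat(pos_l == rid, neg)
            k = int(mask.sum())
            if k:
                neg_t[mask] = pool[rng.integers(pool.size, size=k)]
        return neg_t

    # A fixed corruption set keeps the per-epoch loss comparable across
    # epochs (descent on one finite objective); resampling is opt-in.
    neg_t = draw_corruptions()
    for epoch in range(cfg.epochs):
        if cfg.resample_negatives and epoch > 0:
            neg_t = draw_corruptions()
        h = np.concatenate([pos_h, np.repeat(pos_h, neg)])
        l = np.concatenate([pos_l, np.repeat(pos_l, neg)])
        t = np.concatenate([pos_t, neg_t])
        y = np.concatenate([np.ones(n_pos), -np.ones(n_pos * neg)])

        order = rng.permutation(len(y))
        h, l, t, y = h[order], l[order], t[order], y[order]
        bs = cfg.batch_size if cfg.batch_size > 0 else len(y)
        epoch_loss = 0.0
        for start in range(0, len(y), bs):
            sl = slice(start, start + bs)
            epoch_loss += _sgd_step(emb, h[sl], l[sl], t[sl], y[sl], cfg)
        epoch_loss /= len(y)
        if not np.isfinite(epoch_loss):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
        emb.loss_history.append(epoch_loss)
    return emb


def _sgd_step(
    emb: ComplexEmbeddings,
    h: np.ndarray,
    l: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> float:
    """One SGD update on a batch; returns the summed (unregularised) loss."""
    E, R = emb.entity_table, emb.relation_table
    eh, el, et = E[h], R[l], E[t]

    phi = np.real(np.sum(eh * el * np.conj(et), axis=1))
    margin = y * phi
    # log(1 + exp(-m)), stable
    loss = float(np.sum(np.logaddexp(0.0, -margin)))
    # d loss / d phi = -y * sigmoid(-y*phi); expit is overflow-safe
    dphi = (-y * expit(-margin))[:, None]

    # Wirtinger-style gradients of Re<e_h, e_l, conj(e_t)>
    g_h = dphi * (el * np.conj(et))
    g_l = dphi * (eh * np.conj(et))
    g_t = dphi * np.conj(eh * el)

    grad_E = np.zeros_like(E)
    grad_R = np.zeros_like(R)
    np.add.at(grad_E, h, np.conj(g_h))
    np.add.at(grad_E, t, np.conj(g_t))
    np.add.at(grad_R, l, np.conj(g_l))
    if cfg.reg:
        touched_e = np.unique(np.concatenate([h, t]))
        touched_r = np.unique(l)
        grad_E[touched_e] += 2.0 * cfg.reg * E[touched_e]
        grad_R[touched_r] += 2.0 * cfg.reg * R[touched_r]

    E -= cfg.learning_rate * grad_E
    R -= cfg.learning_rate * grad_R
    return loss


def rank_candidates(
    h: int,
    l: int,
    candidates: Sequence[int],
    emb: ComplexEmbeddings,
) -> list[tuple[int, float]]:
    """Score each candidate tail and sort by descending score.

    Ties are broken by ascending entity id so the ordering is deterministic.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list must be non-empty")
    cands = np.asarray(candidates, dtype=np.int64)
    _check_ids(emb, h, l, int(cands.max()))
    scores = score_triples(np.full(cands.shape, h), np.full(cands.shape, l), cands, emb)
    order = sorted(range(len(cands)), key=lambda i: (-scores[i], cands[i]))
    return [(int(cands[i]), float(scores[i])) for i in order]


# --------------------------------------------------------------------------
# Checkpoint I/O: portable npz (arrays) + JSON sidecar (config, vocab hash)
# --------------------------------------------------------------------------


def save_checkpoint(emb: ComplexEmbeddings, path: str | Path, vocab_hash: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("wb") as fh:
        np.savez(
            fh,
            entity_re=emb.entity_table.real,
            entity_im=emb.entity_table.imag,
            relation_re=emb.relation_table.real,
            relation_im=emb.relation_table.imag,
        )
    meta = {
        "config": asdict(emb.config) if emb.config else None,
        "loss_history": emb.loss_history,
        "vocab_hash": vocab_hash,
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta), encoding="utf-8")
    return path


def load_checkpoint(path: str | Path) -> tuple[ComplexEmbeddings, str]:
    path = Path(path)
    with np.load(path) as data:
        ent = data["entity_re"] + 1j * data["entity_im"]
        rel = data["relation_re"] + 1j * data["relation_im"]
    cfg = None
    vocab_hash = ""
    loss_history: list[float] = []
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        if meta.get("config"):
            cfg = TrainConfig(**meta["config"])
        vocab_hash = meta.get("vocab_hash", "")
        loss_history = meta.get("loss_history", [])
    emb = ComplexEmbeddings(ent, rel, config=cfg, loss_history=loss_history)
    return emb, vocab_hash
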