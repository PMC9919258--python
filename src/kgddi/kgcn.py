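"""Knowledge-graph convolutional embedding of entities.

An entity's representation is computed from its H-hop receptive field: at
every hop, a fixed number N of neighbors is sampled and mixed with softmax
attention weights derived from inner products between a *query* entity's
embedding and the edge-relation embeddings, then combined with the entity's
own vector by an aggregator (sum / concat / neighbor). Training scores a
labeled drug pair as sigmoid(<rep(a | query=b), rep(b | query=a)>) and
minimizes binary cross-entropy; the learned entity table plus aggregator
weights then export one fixed d-dimensional vector per drug (query = the
drug itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from .featurize import EmbeddingSet
from .kg_store import KnowledgeGraph, neighbors

AGGREGATORS = ("sum", "concat", "neighbor")


class KGCNError(ValueError):
    pass


@dataclass
class KGCNConfig:
    dim: int = 64
    neighbor_size: int = 7
    layers: int = 2
    aggregator: str = "concat"
    hidden_activation: str = "relu"
    final_activation: str = "tanh"
    epochs: int = 20
    lr: float = 0.005
    batch_size: int = 256
    patience: int = 5  # early stop on non-improving training loss
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1 or self.neighbor_size < 1 or self.layers < 1:
            raise KGCNError("dim, neighbor_size and layers must all be >= 1")
        if self.aggregator not in AGGREGATORS:
            raise KGCNError(f"aggregator must be one of {AGGREGATORS}")


@dataclass
class KGCNModel:
    entity_table: ag.Tensor  # (E, d)
    relation_table: ag.Tensor  # (R, d)
    layer_W: list  # per layer: (2d, d) for concat, (d, d) otherwise
    layer_b: list  # per layer: (d,)
    cfg: KGCNConfig

    def parameters(self):
        return [self.entity_table, self.relation_table, *self.layer_W, *self.layer_b]


def init_model(kg: KnowledgeGraph, cfg: KGCNConfig, rng: np.random.Generator) -> KGCNModel:
    d = cfg.dim
    ent = ag.Tensor(rng.normal(0.0, 0.1, size=(kg.n_entities, d)), requires_grad=True)
    rel = ag.Tensor(rng.normal(0.0, 0.1, size=(kg.n_relations, d)), requires_grad=True)
    w_in = 2 * d if cfg.aggregator == "concat" else d
    ws, bs = [], []
    for _ in range(cfg.layers):
        lim = np.sqrt(6.0 / (w_in + d))  # Glorot-uniform fan bound
        ws.append(ag.Tensor(rng.uniform(-lim, lim, size=(w_in, d)), requires_grad=True))
        bs.append(ag.Tensor(np.zeros(d), requires_grad=True))
    return KGCNModel(ent, rel, ws, bs, cfg)


# -- reference primitives (plain NumPy) ---------------------------------------

def relation_score(query: np.ndarray, rel: np.ndarray) -> float:
    """Attention logit: inner product of query-entity and relation embeddings."""
    query, rel = np.asarray(query), np.asarray(rel)
    if query.shape != rel.shape:
        raise KGCNError(f"dimension mismatch {query.shape} vs {rel.shape}")
    return float(query @ rel)


def normalize_scores(scores) -> np.ndarray:
    """Max-stabilized softmax over a neighbor-score vector; weights sum to 1."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise KGCNError("cannot normalize an empty score vector")
    if not np.isfinite(scores).all():
        raise KGCNError("non-finite attention scores")
    e = np.exp(scores - scores.max())
    return e / e.sum()


def neighborhood_mix(weights, neighbor_embs) -> np.ndarray:
    """Attention-weighted sum of sampled-neighbor embeddings."""
    weights = np.asarray(weights, dtype=np.float64)
    embs = np.asarray(neighbor_embs, dtype=np.float64)
    if len(weights) != len(embs):
        raise KGCNError(f"{len(weights)} weights for {len(embs)} neighbor embeddings")
    return weights @ embs


def _act(name: str, x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) if name == "relu" else np.tanh(x)


def aggregate(self_emb, mix, W, b, kind: str, activation: str = "relu") -> np.ndarray:
    """Combine an entity's own embedding with its neighborhood mix.

    sum      -> act(W (self + mix) + b)
    concat   -> act(W [self | mix] + b)
    neighbor -> act(W mix + b)          (self embedding ignored)
    """
    self_emb, mix = np.asarray(self_emb, float), np.asarray(mix, float)
    W, b = np.asarray(W, float), np.asarray(b, float)
    if kind == "sum":
        z = (self_emb + mix) @ W
    elif kind == "concat":
        z = np.concatenate([self_emb, mix]) @ W
    elif kind == "neighbor":
        z = mix @ W
    else:
        raise KGCNError(f"unknown aggregator {kind!r}")
    return _act(activation, z + b)


def entity_representation(
    kg: KnowledgeGraph,
    model: KGCNModel,
    root: int,
    query: int,
    cfg: KGCNConfig | None = None,
    rng: np.random.Generator | None = None,
    sample: bool = True,
) -> np.ndarray:
    """Single-entity H-hop representation (reference path, plain NumPy).

    With ``sample=False`` the full neighborhood is used at every hop
    (variable-size receptive field, deterministic); otherwise fixed-size
    fields of width N are drawn from ``rng``.
    """
    from .kg_store import sample_neighbors

    cfg = cfg or model.cfg
    if sample and rng is None:
        rng = np.random.default_rng(cfg.seed)
    ent = model.entity_table.data
    rel = model.relation_table.data
    q = ent[query]
    H = cfg.layers
    if not neighbors(kg, root):
        raise KGCNError(f"entity {root} is isolated; cannot build a receptive field")

    # receptive field: fields[h] lists entities at hop h; edges[h] the
    # (relation, child-slice) structure linking hop h to hop h+1
    fields: list[list[int]] = [[root]]
    edge_rel: list[list[np.ndarray]] = []
    edge_child: list[list[list[int]]] = []
    for h in range(H):
        rels_h, childs_h, nxt = [], [], []
        for v in fields[h]:
            nb = (
                sample_neighbors(kg, v, cfg.neighbor_size, rng)
                if sample
                else neighbors(kg, v)
            )
            if not nb:
                raise KGCNError(f"entity {v} is isolated; cannot build a receptive field")
            rels_h.append(np.array([r for r, _ in nb]))
            childs_h.append([e for _, e in nb])
            nxt.extend(e for _, e in nb)
        edge_rel.append(rels_h)
        edge_child.append(childs_h)
        fields.append(nxt)

    vectors = [[ent[v].copy() for v in fields[h]] for h in range(H + 1)]
    for layer in range(H):
        act = cfg.final_activation if layer == H - 1 else cfg.hidden_activation
        W, b = model.layer_W[layer].data, model.layer_b[layer].data
        new_vectors = []
        for h in range(H - layer):
            updated, offset = [], 0
            for i, v in enumerate(fields[h]):
                k = len(edge_child[h][i])
                nbr_vecs = vectors[h + 1][offset:offset + k]
                offset += k
                w_att = normalize_scores([relation_score(q, rel[r]) for r in edge_rel[h][i]])
                mix = neighborhood_mix(w_att, nbr_vecs)
                updated.append(aggregate(vectors[h][i], mix, W, b, cfg.aggregator, act))
            new_vectors.append(updated)
        vectors = new_vectors
    return vectors[0][0]


# -- batched training path (autodiff) -----------------------------------------

class _AdjacencyIndex:
    """Degree-padded neighbor matrices for vectorized receptive-field sampling."""

    def __init__(self, kg: KnowledgeGraph):
        self.degree = np.zeros(kg.n_entities, dtype=np.int64)
        for v, nbrs in kg.adjacency.items():
            self.degree[v] = len(nbrs)
        dmax = max(1, int(self.degree.max()))
        self.rel_pad = np.zeros((kg.n_entities, dmax), dtype=np.int64)
        self.ent_pad = np.zeros((kg.n_entities, dmax), dtype=np.int64)
        for v, nbrs in kg.adjacency.items():
            if nbrs:
                arr = np.array(nbrs, dtype=np.int64)
                self.rel_pad[v, : len(nbrs)] = arr[:, 0]
                self.ent_pad[v, : len(nbrs)] = arr[:, 1]

    def __contains__(self, v) -> bool:
        return 0 <= v < len(self.degree) and self.degree[v] > 0


def _adjacency_arrays(kg: KnowledgeGraph) -> _AdjacencyIndex:
    return _AdjacencyIndex(kg)


def _sample_field(adj: _AdjacencyIndex, roots: np.ndarray, H: int, N: int,
                  rng: np.random.Generator):
    """Fixed-width receptive field: ents[h] is (B, N^h), rels[h] is (B, N^(h+1)).

    Uniform without replacement where degree >= N (random-key top-N), with
    replacement otherwise.
    """
    ents = [np.asarray(roots, dtype=np.int64).reshape(-1, 1)]
    rels = []
    b = ents[0].shape[0]
    dmax = adj.rel_pad.shape[1]
    cols = np.arange(dmax)
    for _ in range(H):
        prev = ents[-1].reshape(-1)
        deg = adj.degree[prev]
        if (deg == 0).any():
            bad = int(prev[deg == 0][0])
            raise KGCNError(f"entity {bad} is isolated; cannot build a receptive field")
        keys = rng.random((prev.size, dmax))
        keys[cols[None, :] >= deg[:, None]] = np.inf  # mask the padding slots
        sub = np.argpartition(keys, min(N, dmax) - 1, axis=1)[:, :N]
        if N > dmax:
            sub = np.concatenate([sub, sub[:, : N - dmax]], axis=1)[:, :N]
        wr = rng.integers(0, deg[:, None], size=(prev.size, N))  # with-replacement draw
        idx = np.where((deg >= N)[:, None], sub, wr)
        r_out = np.take_along_axis(adj.rel_pad[prev], idx, axis=1)
        e_out = np.take_along_axis(adj.ent_pad[prev], idx, axis=1)
        rels.append(r_out.reshape(b, -1))
        ents.append(e_out.reshape(b, -1))
    return ents, rels


def _act_t(name: str, x: ag.Tensor) -> ag.Tensor:
    return ag.relu(x) if name == "relu" else ag.tanh(x)


def _attention_scores(rel_e: ag.Tensor, q: ag.Tensor) -> ag.Tensor:
    """Fused <relation, query> contraction: (B,m,N,d),(B,1,1,d) -> (B,m,N)."""
    a, b = rel_e.data, q.data

    def bwd(g, out):
        ga = g[..., None] * b
        gb = np.einsum("bmn,bmnd->bd", g, a)[:, None, None, :]
        return (ga, gb)

    return ag.Tensor._from_op(np.einsum("bmnd,bijd->bmn", a, b), (rel_e, q), bwd)


def _weighted_mix(w: ag.Tensor, nbr: ag.Tensor) -> ag.Tensor:
    """Fused attention mix: (B,m,N),(B,m,N,d) -> (B,m,d)."""
    a, b = w.data, nbr.data

    def bwd(g, out):
        gw = np.einsum("bmd,bmnd->bmn", g, b)
        gn = a[..., None] * g[:, :, None, :]
        return (gw, gn)

    return ag.Tensor._from_op(np.einsum("bmn,bmnd->bmd", a, b), (w, nbr), bwd)


def _batch_representation(model: KGCNModel, ents, rels, queries: np.ndarray) -> ag.Tensor:
    """Differentiable H-hop aggregation over a pre-sampled receptive field."""
    cfg = model.cfg
    H, N, d = cfg.layers, cfg.neighbor_size, cfg.dim
    B = ents[0].shape[0]
    q = ag.gather(model.entity_table, np.asarray(queries)).reshape(B, 1, 1, d)
    vectors = [ag.gather(model.entity_table, ents[h]) for h in range(H + 1)]
    for layer in range(H):
        act = cfg.final_activation if layer == H - 1 else cfg.hidden_activation
        W, b = model.layer_W[layer], model.layer_b[layer]
        new_vectors = []
        for h in range(H - layer):
            m = N**h
            rel_e = ag.gather(model.relation_table, rels[h]).reshape(B, m, N, d)
            scores = _attention_scores(rel_e, q)  # (B, m, N)
            w_att = ag.softmax(scores, axis=-1)
            nbr = vectors[h + 1].reshape(B, m, N, d)
            mix = _weighted_mix(w_att, nbr)  # (B, m, d)
            self_v = vectors[h]
            if cfg.aggregator == "sum":
                z = (self_v + mix) @ W
            elif cfg.aggregator == "concat":
                z = ag.concat([self_v, mix], axis=-1) @ W
            else:
                z = mix @ W
            new_vectors.append(_act_t(act, z + b))
        vectors = new_vectors
    return vectors[0].reshape(B, cfg.dim)


def _pair_logits(model, adj, pairs: np.ndarray, rng) -> ag.Tensor:
    cfg = model.cfg
    a, b = pairs[:, 0], pairs[:, 1]
    roots = np.concatenate([a, b])
    queries = np.concatenate([b, a])
    ents, rels = _sample_field(adj, roots, cfg.layers, cfg.neighbor_size, rng)
    rep = _batch_representation(model, ents, rels, queries)
    n = len(a)
    rep_a = ag.Tensor._from_op(rep.data[:n], (rep,), lambda g, out: (np.concatenate([g, np.zeros((n, g.shape[1]))]),))
    rep_b = ag.Tensor._from_op(rep.data[n:], (rep,), lambda g, out: (np.concatenate([np.zeros((n, g.shape[1])), g]),))
    return (rep_a * rep_b).sum(axis=-1)


def _bce(logits: ag.Tensor, y: np.ndarray) -> ag.Tensor:
    p = ag.sigmoid(logits)
    eps = 1e-12
    return -(
        ag.Tensor(y) * (p + eps).log() + ag.Tensor(1.0 - y) * (1.0 - p + eps).log()
    ).mean()


def train_kgcn(
    kg: KnowledgeGraph,
    positives,
    negatives,
    cfg: KGCNConfig | None = None,
) -> tuple[KGCNModel, list[float]]:
    """Fit entity/relation embeddings on labeled drug pairs.

    Minimizes BCE of sigmoid(<rep(a|q=b), rep(b|q=a)>) with Adam; receptive
    fields are resampled every epoch. Returns the model and per-epoch mean
    training loss. Deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or KGCNConfig()
    if not positives or not negatives:
        raise KGCNError("training requires both positive and negative pairs")
    rng = np.random.default_rng(cfg.seed)
    model = init_model(kg, cfg, rng)
    adj = _adjacency_arrays(kg)
    pairs = np.array([[a, b] for a, b in list(positives) + list(negatives)], dtype=np.int64)
    for v in np.unique(pairs):
        if int(v) not in adj:
            raise KGCNError(f"drug entity {v} is isolated in the KG; filter it upstream")
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    opt = ag.Adam(model.parameters(), lr=cfg.lr)
    log: list[float] = []
    best, since_best = np.inf, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(pairs), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            logits = _pair_logits(model, adj, pairs[sel], rng)
            loss = _bce(logits, y[sel])
            if not np.isfinite(loss.data):
                raise KGCNError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        epoch_loss = float(np.mean(losses))
        log.append(epoch_loss)
        if epoch_loss < best - 1e-6:
            best, since_best = epoch_loss, 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    return model, log


def score_pairs(
    model: KGCNModel, kg: KnowledgeGraph, pairs, rng: np.random.Generator | None = None
) -> np.ndarray:
    """KGCN-only pair probabilities: sigmoid of the representation inner product."""
    cfg = model.cfg
    rng = rng or np.random.default_rng(cfg.seed)
    adj = _adjacency_arrays(kg)
    arr = np.array([[a, b] for a, b in pairs], dtype=np.int64)
    logits = _pair_logits(model, adj, arr, rng)
    return 0.5 * (1.0 + np.tanh(0.5 * logits.data))


def export_embeddings(
    model: KGCNModel, kg: KnowledgeGraph, drug_ids=None
) -> tuple[EmbeddingSet, list[int]]:
    """One d-vector per drug entity, computed with query = the entity itself.

    Receptive-field sampling is frozen by the config seed so repeated exports
    are identical. Drugs with no KG neighbors are excluded and returned in
    the second element for the caller to log.
    """
    cfg = model.cfg
    adj = _adjacency_arrays(kg)
    ids = list(kg.drug_ids()) if drug_ids is None else list(drug_ids)
    kept = [v for v in ids if v in adj]
    skipped = [v for v in ids if v not in adj]
    rng = np.random.default_rng(cfg.seed)
    vectors = {}
    for start in range(0, len(kept), 512):
        chunk = np.array(kept[start:start + 512], dtype=np.int64)
        ents, rels = _sample_field(adj, chunk, cfg.layers, cfg.neighbor_size, rng)
        rep = _batch_representation(model, ents, rels, chunk)
        for v, vec in zip(chunk, rep.data):
            vectors[int(v)] = vec
    return EmbeddingSet(cfg.dim, vectors), skipped
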