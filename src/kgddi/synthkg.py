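"""Deterministic synthetic knowledge-graph worlds with planted DDI signal.

Every drug carries a hidden latent vector drawn around one of a few cluster
prototypes (a simplex, so same-cluster inner products are large and positive
while cross-cluster products are negative). The same latents drive all three
observable channels, so every stage of the pipeline has learnable signal:

* KG edges   — drugs wire to protein/gene/disease anchor entities with
               probability increasing in latent similarity (softmax
               selection), plus structural-analog drug-drug edges inside a
               cluster and anchor-anchor edges, giving 8 relation types that
               mirror a curated pharmacology KG schema at reduced scale;
* labels     — pair (a, b) is truly positive with probability
               logistic(beta * <z_a, z_b>), then flipped at the label-noise
               rate; only a fraction of noisy positives is *revealed* as
               labeled, the rest joins the unlabeled pool (the PU setting);
* fingerprints — cluster-prototype bit patterns flipped independently per
               bit, so chemistry-space clustering carries the same signal.

Interaction type (increase vs decrease) is the sign of a designated latent
coordinate summed over the pair. The hidden ground truth is written to a
separate file that pipeline code never reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .featurize import FingerprintSet, write_fingerprints
from .kg_store import Entity, KnowledgeGraph, Relation, Triple, build_kg
from .pu_negatives import write_pairs

RELATION_NAMES = (
    "drug_target",
    "drug_enzyme",
    "drug_gene",
    "drug_disease",
    "drug_drug_similar",
    "protein_protein",
    "protein_disease",
    "gene_disease",
)


class SynthError(ValueError):
    pass


@dataclass
class SynthConfig:
    n_drugs: int = 300
    n_proteins: int = 120
    n_genes: int = 80
    n_diseases: int = 60
    n_clusters: int = 4
    # skewed cluster sizes concentrate positives in fingerprint space, the
    # premise of the distance-based reliable-negative rule
    cluster_weights: tuple = (0.65, 0.15, 0.10, 0.10)
    latent_dim: int = 8
    latent_noise: float = 0.15
    edges_per_relation: int = 2  # drug->anchor edges per drug-* relation type
    similar_edges: int = 2  # drug-drug structural-analog edges per drug
    edge_gamma: float = 2.0  # softmax sharpness of anchor selection
    fp_width: int = 64
    bit_flip: float = 0.08
    n_pairs: int = 5000
    same_cluster_frac: float = 0.75
    beta: float = 5.0  # label-rule sharpness; 0 = null world
    interaction_offset: float = 1.0  # inner-product level at which P(pos) = 1/2
    # hidden per-drug activity shifting the pair logit: visible neither in
    # fingerprints nor in KG wiring, so it is learnable only through per-drug
    # recurrence across training pairs — the signal component that cold-start
    # (pairwise-disjoint) splits remove
    drug_effect_sd: float = 0.4
    active_scale: float = 1.3  # prototype norm of the interacting cluster
    inactive_scale: float = 0.6  # prototype norm of the remaining clusters
    label_noise: float = 0.10
    reveal_fraction: float = 0.5  # fraction of noisy positives labeled
    type_coord: int = 0  # latent coordinate whose pair-sum sign sets itype
    type_bits: int = 6  # trailing fingerprint bits that encode the type sign
    seed: int = 0

    def __post_init__(self):
        for name in ("n_drugs", "n_proteins", "n_genes", "n_diseases", "n_clusters", "latent_dim"):
            if getattr(self, name) < 1:
                raise SynthError(f"{name} must be >= 1")
        for name in ("bit_flip", "label_noise", "reveal_fraction", "same_cluster_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SynthError(f"{name} must be in [0, 1]")
        w = np.asarray(self.cluster_weights, dtype=float)
        if w.shape != (self.n_clusters,) or (w <= 0).any():
            raise SynthError("cluster_weights must be n_clusters positive numbers")
        object.__setattr__(self, "cluster_weights", tuple(w / w.sum()))


@dataclass
class SynthWorld:
    cfg: SynthConfig
    kg: KnowledgeGraph
    fingerprints: FingerprintSet  # keyed by drug name
    pairs: list  # ((name_a, name_b), label or None, itype or None)
    truth: list  # (name_a, name_b, true_label, noisy_label, itype)
    latents: np.ndarray = field(repr=False)  # (n_drugs, m)
    clusters: np.ndarray = field(repr=False)  # (n_drugs,)
    drug_effects: np.ndarray = field(repr=False)  # (n_drugs,) hidden activity


def _simplex_prototypes(c: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """c unit-norm prototypes with pairwise inner product -1/(c-1) (regular simplex)."""
    if c == 1:
        v = rng.normal(size=m)
        return (v / np.linalg.norm(v))[None, :]
    basis = np.linalg.qr(rng.normal(size=(m, m)))[0][:, :c]  # orthonormal columns
    eye = np.eye(c)
    centered = eye - eye.mean(axis=0)
    protos = centered @ basis.T  # rows in the simplex hyperplane
    return protos / np.linalg.norm(protos, axis=1, keepdims=True)


def _logistic(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def generate(cfg: SynthConfig | None = None) -> SynthWorld:
    """Build a SynthWorld; bitwise-reproducible from the same config."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    m, C = cfg.latent_dim, cfg.n_clusters
    if m - 1 < C - 1:
        raise SynthError("latent_dim must be at least n_clusters")
    # prototypes live in the coordinates other than type_coord, so the type
    # coordinate stays noise-only (types end up balanced across clusters);
    # cluster 0 is the pharmacologically "active" one: its larger norm puts
    # its same-cluster inner products above interaction_offset, all others below
    sub = _simplex_prototypes(C, m - 1, rng)
    sub[0] *= cfg.active_scale
    sub[1:] *= cfg.inactive_scale
    protos = np.insert(sub, cfg.type_coord, 0.0, axis=1)

    weights = np.asarray(cfg.cluster_weights)
    clusters = rng.choice(C, size=cfg.n_drugs, p=weights)
    latents = protos[clusters] + cfg.latent_noise * rng.normal(size=(cfg.n_drugs, m))
    drug_effects = cfg.drug_effect_sd * rng.normal(size=cfg.n_drugs)

    # -- entities: drugs first, then protein/gene/disease anchors ------------
    drug_names = [f"drug_{i:04d}" for i in range(cfg.n_drugs)]
    entities = [Entity(i, n, "drug") for i, n in enumerate(drug_names)]
    anchor_latents: dict[str, np.ndarray] = {}
    anchor_ids: dict[str, np.ndarray] = {}
    anchor_clusters: dict[str, np.ndarray] = {}
    offset = cfg.n_drugs
    for etype, count in (
        ("protein", cfg.n_proteins),
        ("gene", cfg.n_genes),
        ("disease", cfg.n_diseases),
    ):
        acl = rng.choice(C, size=count, p=weights)
        anchor_clusters[etype] = acl
        anchor_latents[etype] = protos[acl] + cfg.latent_noise * rng.normal(size=(count, m))
        anchor_ids[etype] = np.arange(offset, offset + count)
        entities.extend(
            Entity(offset + j, f"{etype[:4]}_{j:04d}", etype) for j in range(count)
        )
        offset += count

    relations = [Relation(i, n) for i, n in enumerate(RELATION_NAMES)]
    rel_id = {n: i for i, n in enumerate(RELATION_NAMES)}

    # -- edges ----------------------------------------------------------------
    def pick_anchors(z: np.ndarray, etype: str, k: int) -> np.ndarray:
        sims = anchor_latents[etype] @ z
        w = np.exp(cfg.edge_gamma * (sims - sims.max()))
        w /= w.sum()
        k = min(k, len(w))
        return rng.choice(anchor_ids[etype], size=k, replace=False, p=w)

    anchor_of_rel = {
        "drug_target": "protein",
        "drug_enzyme": "protein",
        "drug_gene": "gene",
        "drug_disease": "disease",
    }
    triples: list[Triple] = []
    for attempt in range(100):
        drug_triples: list[Triple] = []
        for i in range(cfg.n_drugs):
            for rname, etype in anchor_of_rel.items():
                for a in pick_anchors(latents[i], etype, cfg.edges_per_relation):
                    drug_triples.append(Triple(i, rel_id[rname], int(a)))
            mates = np.flatnonzero((clusters == clusters[i]) & (np.arange(cfg.n_drugs) != i))
            if mates.size:
                for j in rng.choice(mates, size=min(cfg.similar_edges, mates.size), replace=False):
                    drug_triples.append(Triple(i, rel_id["drug_drug_similar"], int(j)))
        touched = {t.head for t in drug_triples} | {t.tail for t in drug_triples}
        if all(i in touched for i in range(cfg.n_drugs)):
            break
    else:
        raise SynthError("could not wire every drug after 100 attempts")
    triples.extend(drug_triples)

    def same_cluster_anchor_edges(etype_a, etype_b, rname, prob):
        cl_a = anchor_clusters[etype_a]
        cl_b = anchor_clusters[etype_b]
        for j, ca in enumerate(cl_a):
            if rng.random() > prob:
                continue
            mates = np.flatnonzero(cl_b == ca)
            if etype_a == etype_b:
                mates = mates[mates != j]
            if mates.size:
                k = int(rng.choice(mates))
                triples.append(
                    Triple(int(anchor_ids[etype_a][j]), rel_id[rname], int(anchor_ids[etype_b][k]))
                )

    same_cluster_anchor_edges("protein", "protein", "protein_protein", 0.8)
    same_cluster_anchor_edges("protein", "disease", "protein_disease", 0.5)
    same_cluster_anchor_edges("gene", "disease", "gene_disease", 0.5)

    kg = build_kg(entities, relations, triples)

    # -- fingerprints ---------------------------------------------------------
    proto_bits = rng.integers(0, 2, size=(C, cfg.fp_width))
    flips = rng.random(size=(cfg.n_drugs, cfg.fp_width)) < cfg.bit_flip
    bits = np.where(flips, 1 - proto_bits[clusters], proto_bits[clusters])
    if cfg.type_bits > 0:
        # trailing bits carry the interaction-type latent (same per-bit noise)
        tsign = (latents[:, cfg.type_coord] > 0).astype(int)[:, None]
        tb = min(cfg.type_bits, cfg.fp_width)
        bits[:, -tb:] = np.where(flips[:, -tb:], 1 - tsign, tsign)
    fps = FingerprintSet(cfg.fp_width, {drug_names[i]: bits[i] for i in range(cfg.n_drugs)})

    # -- labeled pairs --------------------------------------------------------
    n_same = int(round(cfg.n_pairs * cfg.same_cluster_frac))
    chosen: set[tuple[int, int]] = set()
    pair_list: list[tuple[int, int]] = []
    guard = 0
    while len(pair_list) < cfg.n_pairs and guard < 100 * cfg.n_pairs:
        guard += 1
        want_same = len(pair_list) < n_same
        a = int(rng.integers(cfg.n_drugs))
        pool = np.flatnonzero(
            (clusters == clusters[a]) if want_same else (clusters != clusters[a])
        )
        pool = pool[pool != a]
        if not pool.size:
            continue
        b = int(rng.choice(pool))
        key = (min(a, b), max(a, b))
        if key in chosen:
            continue
        chosen.add(key)
        pair_list.append(key)
    if len(pair_list) < cfg.n_pairs:
        raise SynthError("could not sample enough distinct drug pairs; lower n_pairs")

    pairs_out, truth_out = [], []
    for a, b in pair_list:
        logit = float(latents[a] @ latents[b]) + drug_effects[a] + drug_effects[b]
        p_pos = _logistic(cfg.beta * (logit - cfg.interaction_offset))
        true_label = int(rng.random() < p_pos)
        noisy = true_label ^ int(rng.random() < cfg.label_noise)
        itype = "increase" if (latents[a] + latents[b])[cfg.type_coord] > 0 else "decrease"
        na, nb = drug_names[a], drug_names[b]
        truth_out.append((na, nb, true_label, noisy, itype))
        if noisy == 1 and rng.random() < cfg.reveal_fraction:
            pairs_out.append(((na, nb), 1, itype))
        else:
            pairs_out.append(((na, nb), None, None))

    return SynthWorld(cfg, kg, fps, pairs_out, truth_out, latents, clusters, drug_effects)


def write_world(world: SynthWorld, out_dir) -> dict[str, Path]:
    """Write the four pipeline TSVs plus the ground-truth file.

    ``truth.tsv`` exists only for test oracles; no pipeline loader reads it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.tsv" for name in
             ("triples", "entities", "fingerprints", "pairs", "truth")}
    with open(paths["entities"], "w", encoding="utf-8") as fh:
        for e in world.kg.entities:
            fh.write(f"{e.id}\t{e.name}\t{e.etype}\n")
    names = {e.id: e.name for e in world.kg.entities}
    rnames = {r.id: r.name for r in world.kg.relations}
    with open(paths["triples"], "w", encoding="utf-8") as fh:
        for t in world.kg.triples:
            fh.write(f"{names[t.head]}\t{rnames[t.relation]}\t{names[t.tail]}\n")
    write_fingerprints(world.fingerprints, paths["fingerprints"])
    write_pairs(world.pairs, paths["pairs"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("# drug_a\tdrug_b\ttrue_label\tnoisy_label\titype\n")
        for na, nb, tl, nl, it in world.truth:
            fh.write(f"{na}\t{nb}\t{tl}\t{nl}\t{it}\n")
    return paths
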