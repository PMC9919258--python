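"""End-to-end orchestration: config, seeding, logging, and the full
select-negatives -> train-KGCN -> featurize -> train-NFM -> evaluate run.

A single master seed fans out to per-stage seeds by stable stage-name
hashing, so any stage can be re-run in isolation and two runs with the same
master seed produce bitwise-identical metric reports. Each run writes a
manifest (config snapshot, input checksums, timings, warnings, report path)
sufficient to replay it exactly.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evalx, featurize, kgcn, nfm, pu_negatives, synthkg
from .kg_store import KnowledgeGraph, load_triples

log = logging.getLogger("kgddi")


class ConfigError(ValueError):
    pass


def default_config() -> dict:
    """Full default run configuration.

    Model hyperparameters carry the published defaults (d=64, N=7, H=2,
    concat aggregator, NFM latent width 64, lr=0.005, Task-2 batch 1250,
    reliable-negative threshold n=1.2, 10-fold CV); the synthetic-world block
    carries this package's study conditions; `cv.repeats` defaults to 1 at
    synthetic scale.
    """
    return {
        "seed": 0,
        "out_dir": "runs/run0",
        "inputs": {  # all None -> generate a synthetic world instead
            "triples": None,
            "entities": None,
            "pairs": None,
            "fingerprints": None,
            "smiles": None,
        },
        "synth": {
            k: getattr(synthkg.SynthConfig(), k)
            for k in synthkg.SynthConfig.__dataclass_fields__
        },
        "negatives": {"strategy": "reliable", "n": 1.2, "ratio": 1.0},
        "kgcn": {
            "dim": 64,
            "neighbor_size": 7,
            "layers": 2,
            "aggregator": "concat",
            "epochs": 12,
            "lr": 0.005,
            "batch_size": 256,
            "patience": 5,
        },
        "nfm": {"latent_dim": 64, "lr": 0.005, "epochs": 20, "batch_size": 1024},
        "task2": {"enabled": False, "lr": 0.005, "epochs": 20, "batch_size": 1250},
        "features": {"use_fingerprints": True, "use_embeddings": True, "kgcn_only": False},
        "cv": {
            "mode": "kfold",  # kfold | pwcv
            "k": 10,
            "repeats": 1,
            "threshold": 0.5,
            "embeddings": "per-fold",  # per-fold | frozen
            "pwcv_mode": "both-unseen",
        },
    }


def _merge_strict(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}{key}"
        if key not in base:
            raise ConfigError(f"unknown config key {here!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge_strict(base[key], val, here + ".")
        else:
            out[key] = val
    return out


def validate_config(config) -> dict:
    """Normalize a config (dict or YAML path): fill defaults, reject unknown
    keys and out-of-range values."""
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge_strict(default_config(), config)
    if cfg["negatives"]["n"] <= 0:
        raise ConfigError("negatives.n must be > 0")
    if cfg["negatives"]["strategy"] not in ("reliable", "random"):
        raise ConfigError("negatives.strategy must be reliable or random")
    if cfg["kgcn"]["neighbor_size"] < 1 or cfg["kgcn"]["layers"] < 1 or cfg["kgcn"]["dim"] < 1:
        raise ConfigError("kgcn dim/neighbor_size/layers must be >= 1")
    if cfg["cv"]["mode"] not in ("kfold", "pwcv"):
        raise ConfigError("cv.mode must be kfold or pwcv")
    if cfg["cv"]["embeddings"] not in ("per-fold", "frozen"):
        raise ConfigError("cv.embeddings must be per-fold or frozen")
    if not cfg["features"]["use_fingerprints"] and not cfg["features"]["use_embeddings"]:
        if not cfg["features"]["kgcn_only"]:
            raise ConfigError("at least one feature block (or kgcn_only) must be enabled")
    return cfg


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict
    timings: dict
    warnings: list
    report: evalx.MetricReport | None
    report_path: str | None
    stage_log: dict = field(default_factory=dict)
    task2_accuracy: float | None = None

    def to_json(self) -> dict:
        out = {
            "config": self.config,
            "input_checksums": self.input_checksums,
            "timings": self.timings,
            "warnings": self.warnings,
            "report_path": self.report_path,
            "stage_log": self.stage_log,
            "task2_accuracy": self.task2_accuracy,
        }
        if self.report is not None:
            out["metrics_mean"] = self.report.mean
            out["metrics_rsd"] = self.report.rsd
        return out


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class Dataset:
    """Resolved, id-keyed inputs ready for training."""

    kg: KnowledgeGraph
    fps: featurize.FingerprintSet  # keyed by entity id
    pairs: list  # canonical (a, b) id tuples, labeled
    labels: np.ndarray
    itypes: list  # parallel to pairs; None where untyped
    selection: pu_negatives.NegativeSelection | None
    warnings: list


def _build_dataset(cfg: dict, out_dir: Path) -> Dataset:
    warnings: list[str] = []
    inputs = cfg["inputs"]
    if inputs["triples"] is None:
        scfg = synthkg.SynthConfig(**cfg["synth"])
        world = synthkg.generate(scfg)
        paths = synthkg.write_world(world, out_dir / "data")
        kg = world.kg
        fps_named = world.fingerprints
        pair_rows = world.pairs
        log.info("synthetic world: %d entities, %d triples, %d pairs",
                 kg.n_entities, len(kg.triples), len(pair_rows))
    else:
        kg = load_triples(inputs["triples"], inputs["entities"])
        if inputs["fingerprints"]:
            fps_named = featurize.load_fingerprints(inputs["fingerprints"])
        else:
            fps_named, rejected = featurize.compute_fingerprints(inputs["smiles"])
            if rejected:
                warnings.append(f"unparseable SMILES for {len(rejected)} drugs: "
                                + ",".join(n for n, _ in rejected[:10]))
        pair_rows = pu_negatives.load_pairs(inputs["pairs"])

    name_to_id = kg.name_to_id()
    for (a, b), _lab, _it in pair_rows:
        if a not in name_to_id or b not in name_to_id:
            missing = a if a not in name_to_id else b
            raise ConfigError(f"pair file references drug {missing!r} absent from the KG")
    fps = fps_named.relabel(name_to_id)

    def canon(a, b):
        ia, ib = name_to_id[a], name_to_id[b]
        return (ia, ib) if ia <= ib else (ib, ia)

    positives, pos_itypes, unlabeled, explicit_negs = [], [], [], []
    for (a, b), lab, itype in pair_rows:
        key = canon(a, b)
        if lab == 1:
            positives.append(key)
            pos_itypes.append(itype)
        elif lab == 0:
            explicit_negs.append(key)
        else:
            unlabeled.append(key)
    if not positives:
        raise ConfigError("no labeled positive pairs in input")
    missing_fp = [p for p in {d for pr in positives + unlabeled for d in pr} if p not in fps]
    if missing_fp:
        raise ConfigError(f"drugs missing fingerprints: {sorted(missing_fp)[:5]}")

    rng = np.random.default_rng(derive_seed(cfg["seed"], "negatives"))
    selection = None
    n_wanted = int(round(cfg["negatives"]["ratio"] * len(positives))) - len(explicit_negs)
    n_wanted = max(n_wanted, 0)
    if not unlabeled:
        negatives = explicit_negs
        pairs = positives + negatives
        labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
        itypes = pos_itypes + [None] * len(negatives)
        return Dataset(kg, fps, pairs, labels, itypes, None, warnings)
    if cfg["negatives"]["strategy"] == "reliable":
        center = pu_negatives.cluster_center(positives, fps)
        selection = pu_negatives.select_negatives(
            unlabeled, center, cfg["negatives"]["n"], fps
        )
        pool = sorted(selection.selected)
        log.info("reliable negatives: AED=%.4f D=%.4f selected=%d/%d",
                 selection.aed, selection.threshold, len(pool), len(unlabeled))
    else:
        pool = sorted(unlabeled)
    if len(pool) < n_wanted:
        warnings.append(
            f"reliable-negative pool ({len(pool)}) smaller than requested {n_wanted}; using all"
        )
        negatives = explicit_negs + list(pool)
    else:
        idx = rng.choice(len(pool), size=n_wanted, replace=False)
        negatives = explicit_negs + [pool[i] for i in idx]

    pairs = positives + negatives
    labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    itypes = pos_itypes + [None] * len(negatives)
    return Dataset(kg, fps, pairs, labels, itypes, selection, warnings)


def _features_for(cfg, ds: Dataset, embs, pair_list, both_orders: bool):
    """Assemble the NFM design matrix for pair_list; optionally both orders."""
    use_fp = cfg["features"]["use_fingerprints"]
    use_emb = cfg["features"]["use_embeddings"]
    rows = []
    for a, b in pair_list:
        orders = [(a, b), (b, a)] if both_orders else [(a, b)]
        for x, yv in orders:
            blocks = []
            if use_fp:
                blocks += [ds.fps[x], ds.fps[yv]]
            if use_emb:
                ex = embs[x] if x in embs else np.zeros(embs.dim)
                ey = embs[yv] if yv in embs else np.zeros(embs.dim)
                blocks += [ex, ey]
            rows.append(np.concatenate(blocks))
    return np.stack(rows)


def _make_trainer(cfg: dict, ds: Dataset, stage_log: dict):
    """Fold trainer closure for evalx.evaluate: (train_idx, test_idx) -> scores."""
    kcfg_base = dict(cfg["kgcn"])
    master = cfg["seed"]
    use_emb = cfg["features"]["use_embeddings"]
    kgcn_only = cfg["features"]["kgcn_only"]
    frozen_model = None

    def train_kgcn_on(idx, seed):
        kcfg = kgcn.KGCNConfig(seed=seed, **kcfg_base)
        pos = [ds.pairs[i] for i in idx if ds.labels[i] == 1]
        neg = [ds.pairs[i] for i in idx if ds.labels[i] == 0]
        model, klog = kgcn.train_kgcn(ds.kg, pos, neg, kcfg)
        stage_log.setdefault("kgcn_loss", []).append(klog)
        return model

    if (use_emb or kgcn_only) and cfg["cv"]["embeddings"] == "frozen":
        frozen_model = train_kgcn_on(np.arange(len(ds.pairs)), derive_seed(master, "kgcn"))

    fold_counter = {"i": 0}

    def trainer(train_idx, test_idx):
        fold = fold_counter["i"]
        fold_counter["i"] += 1
        kseed = derive_seed(master, f"kgcn-fold{fold}")
        model = None
        if use_emb or kgcn_only:
            model = frozen_model or train_kgcn_on(train_idx, kseed)
        if kgcn_only:
            test_pairs = [ds.pairs[i] for i in test_idx]
            rng = np.random.default_rng(derive_seed(master, f"kgcnscore-fold{fold}"))
            return kgcn.score_pairs(model, ds.kg, test_pairs, rng)
        embs = None
        if use_emb:
            embs, skipped = kgcn.export_embeddings(model, ds.kg)
            if skipped:
                log.warning("fold %d: %d drugs had no KG neighbors; embeddings zeroed", fold, len(skipped))
        tr_pairs = [ds.pairs[i] for i in train_idx]
        te_pairs = [ds.pairs[i] for i in test_idx]
        Xtr = _features_for(cfg, ds, embs, tr_pairs, both_orders=True)
        ytr = np.repeat(ds.labels[train_idx], 2)
        ncfg = nfm.NFMConfig(seed=derive_seed(master, f"nfm-fold{fold}"), **cfg["nfm"])
        model_nfm, nlog = nfm.train_nfm(Xtr, ytr, ncfg)
        stage_log.setdefault("nfm_loss", []).append(nlog)
        Xte = _features_for(cfg, ds, embs, te_pairs, both_orders=True)
        scores = nfm.predict(model_nfm, Xte)
        return 0.5 * (scores[0::2] + scores[1::2])  # average the two orderings

    return trainer


def run_all(config, out_dir=None) -> RunManifest:
    """Execute the full pipeline per config; returns the manifest.

    Stages: build dataset (synth or load + reliable negatives) -> CV plan ->
    per-fold KGCN + NFM training and scoring -> metric report (+ optional
    Task-2 type classifier). Deterministic for a fixed master seed.
    """
    cfg = validate_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    timings, stage_log = {}, {}
    t0 = time.time()
    ds = _build_dataset(cfg, out)
    stage_log["n_positives"] = int(ds.labels.sum())
    stage_log["n_negatives"] = int(len(ds.labels) - ds.labels.sum())
    if ds.selection is not None:
        stage_log["aed"] = ds.selection.aed
        stage_log["threshold_D"] = ds.selection.threshold
        stage_log["n_selected"] = len(ds.selection.selected)
    timings["dataset"] = time.time() - t0

    t0 = time.time()
    if cfg["cv"]["mode"] == "kfold":
        plan = evalx.kfold_plan(
            ds.labels, k=cfg["cv"]["k"], repeats=cfg["cv"]["repeats"],
            seed=derive_seed(cfg["seed"], "cv"),
        )
    else:
        plan = evalx.pwcv_plan(
            ds.pairs, k=cfg["cv"]["k"], seed=derive_seed(cfg["seed"], "cv"),
            mode=cfg["cv"]["pwcv_mode"],
        )
        stage_log["pwcv_discarded"] = plan.discarded
    trainer = _make_trainer(cfg, ds, stage_log)
    report = evalx.evaluate(trainer, plan, ds.pairs, ds.labels, cfg["cv"]["threshold"])
    timings["evaluate"] = time.time() - t0

    task2_acc = None
    if cfg["task2"]["enabled"]:
        task2_acc = _run_task2(cfg, ds, stage_log)

    report_path = out / "report.tsv"
    evalx.write_report(report, report_path)
    checksums = {}
    data_dir = out / "data"
    if data_dir.is_dir():
        checksums = {p.name: _checksum(p) for p in sorted(data_dir.glob("*.tsv"))}
    manifest = RunManifest(
        config=cfg, input_checksums=checksums, timings=timings,
        warnings=ds.warnings, report=report, report_path=str(report_path),
        stage_log=stage_log, task2_accuracy=task2_acc,
    )
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest.to_json(), indent=2, default=float))
    tmp.rename(out / "manifest.json")  # atomic publish
    return manifest


def _run_task2(cfg, ds: Dataset, stage_log: dict) -> float:
    """Train the increase/decrease classifier on typed positives; holdout accuracy."""
    typed = [(p, it) for p, it, lab in zip(ds.pairs, ds.itypes, ds.labels)
             if lab == 1 and it in ("increase", "decrease")]
    if len(typed) < 20:
        log.warning("too few typed positives (%d); skipping Task 2", len(typed))
        return float("nan")
    seed = derive_seed(cfg["seed"], "task2")
    rng = np.random.default_rng(seed)
    kcfg = kgcn.KGCNConfig(seed=derive_seed(cfg["seed"], "kgcn"), **cfg["kgcn"])
    pos = [p for p, _ in typed]
    # embeddings for type features come from a KGCN fit on all labeled pairs
    neg = [ds.pairs[i] for i in range(len(ds.pairs)) if ds.labels[i] == 0]
    model, _ = kgcn.train_kgcn(ds.kg, [ds.pairs[i] for i in range(len(ds.pairs)) if ds.labels[i] == 1], neg, kcfg)
    embs, _ = kgcn.export_embeddings(model, ds.kg)
    X = _features_for(cfg, ds, embs, pos, both_orders=False)
    y = np.array([0 if it == "increase" else 1 for _, it in typed])
    order = rng.permutation(len(X))
    n_test = max(1, len(X) // 5)
    te, tr = order[:n_test], order[n_test:]
    tcfg = nfm.Task2Config(seed=seed, lr=cfg["task2"]["lr"],
                           epochs=cfg["task2"]["epochs"], batch_size=cfg["task2"]["batch_size"])
    t2, tlog = nfm.train_task2(X[tr], y[tr], tcfg)
    stage_log["task2_loss"] = tlog
    probs = nfm.task2_predict(t2, X[te])
    acc = float((probs.argmax(axis=1) == y[te]).mean())
    stage_log["task2_n_train"] = int(len(tr))
    return acc


STUDY_CONDITIONS = (
    "full", "null", "random_negatives", "pwcv", "kgcn_only", "nfm_only"
)


def condition_config(name: str, seed: int = 0, out_dir=None) -> dict:
    """Config for one of the package's named study conditions.

    All conditions share the default synthetic world (300 drugs) and model
    hyperparameters; they differ only in the knob under study:

    * ``full``             — the complete pipeline (reliable negatives, KGCN + NFM)
    * ``null``             — no planted signal (beta = 0) and *random* negatives;
                             the distance rule is disabled here because selecting
                             negatives by fingerprint distance manufactures
                             separability even without any label signal
    * ``random_negatives`` — random instead of reliable negative selection
    * ``pwcv``             — cold-start pairwise-disjoint CV (5 drug-folds)
    * ``kgcn_only``        — score pairs by the KGCN inner product alone
    * ``nfm_only``         — fingerprints only, no graph embeddings
    """
    if name not in STUDY_CONDITIONS:
        raise ConfigError(f"unknown study condition {name!r}")
    cfg = default_config()
    cfg["seed"] = int(seed)
    cfg["synth"]["seed"] = int(seed)
    cfg["out_dir"] = str(out_dir) if out_dir else f"runs/{name}"
    if name == "null":
        cfg["synth"]["beta"] = 0.0
        cfg["negatives"]["strategy"] = "random"
    elif name == "random_negatives":
        cfg["negatives"]["strategy"] = "random"
    elif name == "pwcv":
        cfg["cv"].update({"mode": "pwcv", "k": 5})
    elif name == "kgcn_only":
        cfg["features"].update(
            {"use_fingerprints": False, "use_embeddings": False, "kgcn_only": True}
        )
    elif name == "nfm_only":
        cfg["features"]["use_embeddings"] = False
    return cfg


def replay(manifest_path) -> RunManifest:
    """Re-execute a run from its manifest; reproduces the report bit-for-bit."""
    with open(manifest_path, encoding="utf-8") as fh:
        stored = json.load(fh)
    out = Path(manifest_path).parent / "replay"
    return run_all(stored["config"], out_dir=out)
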