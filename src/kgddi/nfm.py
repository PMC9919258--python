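"""Neural factorization machine pair scorer and interaction-type classifier.

Task 1 (is there an interaction?) uses an NFM: a global bias, a per-feature
linear term, and a neural stack over the bi-interaction pooling of scaled
per-feature latent vectors,

    yhat(x) = w0 + sum_i w_i x_i + p^T sigma_L(W_L ... sigma_1(W_1 f_Bi(Vx) + b_1) ... + b_L)

with f_Bi(Vx) = sum_{i<j} (x_i v_i) o (x_j v_j), computed in linear time via
the identity 1/2 [(sum_i u_i)^2 - sum_i u_i^2] with u_i = x_i v_i. The
prediction layer is a sigmoid, so scores are probabilities.

Task 2 (does the interaction increase or decrease effect?) is a feedforward
net with hidden widths 512/256/128/64 and a softmax head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autograd as ag


class NFMError(ValueError):
    pass


@dataclass
class NFMConfig:
    latent_dim: int = 64  # k, width of per-feature latent vectors
    hidden_layers: int = 4
    hidden_units: int = 128
    lr: float = 0.005
    epochs: int = 20
    batch_size: int = 1024
    seed: int = 0
    bi_dropout: float = 0.0  # fixed at 0


@dataclass
class NFMModel:
    w0: ag.Tensor  # scalar global bias
    w: ag.Tensor  # (n_features,) linear weights
    V: ag.Tensor  # (n_features, k) latent vectors
    hidden_W: list
    hidden_b: list
    p: ag.Tensor  # (hidden_units,) prediction head
    cfg: NFMConfig

    @property
    def n_features(self) -> int:
        return self.w.data.shape[0]

    def parameters(self):
        return [self.w0, self.w, self.V, *self.hidden_W, *self.hidden_b, self.p]


def init_nfm(n_features: int, cfg: NFMConfig, rng: np.random.Generator) -> NFMModel:
    k, h = cfg.latent_dim, cfg.hidden_units
    w0 = ag.Tensor(np.zeros(()), requires_grad=True)
    w = ag.Tensor(np.zeros(n_features), requires_grad=True)
    V = ag.Tensor(rng.normal(0.0, 0.01, size=(n_features, k)), requires_grad=True)
    ws, bs = [], []
    fan_in = k
    for _ in range(cfg.hidden_layers):
        lim = np.sqrt(6.0 / (fan_in + h))
        ws.append(ag.Tensor(rng.uniform(-lim, lim, size=(fan_in, h)), requires_grad=True))
        bs.append(ag.Tensor(np.zeros(h), requires_grad=True))
        fan_in = h
    p = ag.Tensor(rng.normal(0.0, 0.01, size=(h,)), requires_grad=True)
    return NFMModel(w0, w, V, ws, bs, p, cfg)


# -- reference primitives ------------------------------------------------------

def embed_features(x, V) -> list[np.ndarray]:
    """Scaled latent vectors {x_i v_i} for the nonzero features of x."""
    x, V = np.asarray(x, float), np.asarray(V, float)
    if x.shape[0] != V.shape[0]:
        raise NFMError(f"{x.shape[0]} features but {V.shape[0]} latent rows")
    return [x[i] * V[i] for i in np.flatnonzero(x)]


def bi_interaction(scaled) -> np.ndarray:
    """Sum of pairwise element-wise products, via 1/2 [(sum u)^2 - sum u^2].

    Empty or singleton input yields the zero vector (no pairs exist).
    """
    if len(scaled) == 0:
        return np.zeros(0)
    u = np.stack([np.asarray(v, float) for v in scaled])
    if len({v.shape for v in map(np.asarray, scaled)}) > 1:
        raise NFMError("ragged latent-vector widths")
    s = u.sum(axis=0)
    return 0.5 * (s * s - (u * u).sum(axis=0))


def _forward_batch(model: NFMModel, X: np.ndarray) -> ag.Tensor:
    """Differentiable batched forward pass; returns pre-sigmoid scores."""
    Xt = ag.Tensor(X)
    linear = Xt @ model.w  # (B,)
    s = Xt @ model.V  # (B, k) = sum_i x_i v_i
    sq = ag.Tensor(X * X) @ (model.V * model.V)  # (B, k) = sum_i (x_i v_i)^2
    z = (s * s - sq) * 0.5
    for W, b in zip(model.hidden_W, model.hidden_b):
        z = ag.relu(z @ W + b)
    return model.w0 + linear + z @ model.p


def nfm_forward(x, model: NFMModel) -> float:
    """Probability for a single pair-feature vector (logistic of the NFM score)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != model.n_features:
        raise NFMError(f"input width {x.shape[0]} != model width {model.n_features}")
    score = _forward_batch(model, x[None, :]).data[0]
    if not np.isfinite(score):
        raise NFMError("non-finite NFM score")
    return float(0.5 * (1.0 + np.tanh(0.5 * score)))


def predict(model: NFMModel, X: np.ndarray) -> np.ndarray:
    """Probabilities for a (B, n_features) matrix of pair vectors."""
    X = np.asarray(X, dtype=np.float64)
    scores = _forward_batch(model, X).data
    return 0.5 * (1.0 + np.tanh(0.5 * scores))


def _bce(logits: ag.Tensor, y: np.ndarray) -> ag.Tensor:
    p = ag.sigmoid(logits)
    eps = 1e-12
    return -(
        ag.Tensor(y) * (p + eps).log() + ag.Tensor(1.0 - y) * (1.0 - p + eps).log()
    ).mean()


def train_nfm(
    X: np.ndarray, y: np.ndarray, cfg: NFMConfig | None = None
) -> tuple[NFMModel, list[float]]:
    """Fit the NFM on pair features X (B, n) and binary labels y with Adam/BCE.

    Per-epoch mean loss is logged; non-finite loss aborts. Deterministic for
    a fixed ``cfg.seed``.
    """
    cfg = cfg or NFMConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise NFMError("training requires both classes present")
    rng = np.random.default_rng(cfg.seed)
    model = init_nfm(X.shape[1], cfg, rng)
    opt = ag.Adam(model.parameters(), lr=cfg.lr)
    log: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            loss = _bce(_forward_batch(model, X[sel]), y[sel])
            if not np.isfinite(loss.data):
                raise NFMError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.append(float(np.mean(losses)))
    return model, log


# -- Task 2: interaction-type classifier --------------------------------------

@dataclass
class Task2Config:
    hidden: tuple[int, ...] = (512, 256, 128, 64)  # ReLU on first three, identity on last
    lr: float = 0.005
    epochs: int = 20
    batch_size: int = 1250
    seed: int = 0


@dataclass
class Task2DNN:
    Ws: list
    bs: list
    cfg: Task2Config

    def parameters(self):
        return [*self.Ws, *self.bs]


def init_task2(n_features: int, cfg: Task2Config, rng: np.random.Generator) -> Task2DNN:
    widths = [n_features, *cfg.hidden, 2]
    Ws, bs = [], []
    for fi, fo in zip(widths[:-1], widths[1:]):
        lim = np.sqrt(6.0 / (fi + fo))
        Ws.append(ag.Tensor(rng.uniform(-lim, lim, size=(fi, fo)), requires_grad=True))
        bs.append(ag.Tensor(np.zeros(fo), requires_grad=True))
    return Task2DNN(Ws, bs, cfg)


def _task2_logits(model: Task2DNN, X: np.ndarray) -> ag.Tensor:
    z = ag.Tensor(X)
    n_hidden = len(model.Ws) - 1
    for i in range(n_hidden):
        z = z @ model.Ws[i] + model.bs[i]
        if i < 3:  # rectifier on the first three hidden layers only
            z = ag.relu(z)
    return z @ model.Ws[-1] + model.bs[-1]


def task2_predict(model: Task2DNN, X: np.ndarray) -> np.ndarray:
    """Softmax probabilities over {increase, decrease}; rows sum to 1."""
    logits = _task2_logits(model, np.asarray(X, float)).data
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def train_task2(
    X: np.ndarray, itype: np.ndarray, cfg: Task2Config | None = None
) -> tuple[Task2DNN, list[float]]:
    """Fit the type classifier (0 = increase, 1 = decrease) with softmax cross-entropy."""
    cfg = cfg or Task2Config()
    X = np.asarray(X, dtype=np.float64)
    yy = np.asarray(itype, dtype=np.int64)
    if len(np.unique(yy)) < 2:
        raise NFMError("Task 2 requires both interaction types present")
    rng = np.random.default_rng(cfg.seed)
    model = init_task2(X.shape[1], cfg, rng)
    opt = ag.Adam(model.parameters(), lr=cfg.lr)
    onehot = np.eye(2)[yy]
    log: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            probs = ag.softmax(_task2_logits(model, X[sel]), axis=-1)
            loss = -((ag.Tensor(onehot[sel]) * (probs + 1e-12).log()).sum(axis=-1)).mean()
            if not np.isfinite(loss.data):
                raise NFMError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.append(float(np.mean(losses)))
    return model, log


# -- checkpointing -------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_nfm(model: NFMModel, path, vocab_hash: str = "") -> None:
    """Versioned checkpoint (npz container) recording config and parameters."""
    with open(path, "wb") as fh:  # file handle keeps the exact filename
        _savez(fh, model, vocab_hash)


def _savez(fh, model, vocab_hash):
    np.savez(
        fh,
        version=CHECKPOINT_VERSION,
        vocab_hash=vocab_hash,
        latent_dim=model.cfg.latent_dim,
        hidden_layers=model.cfg.hidden_layers,
        hidden_units=model.cfg.hidden_units,
        lr=model.cfg.lr,
        epochs=model.cfg.epochs,
        batch_size=model.cfg.batch_size,
        seed=model.cfg.seed,
        w0=model.w0.data,
        w=model.w.data,
        V=model.V.data,
        p=model.p.data,
        **{f"hW{i}": W.data for i, W in enumerate(model.hidden_W)},
        **{f"hb{i}": b.data for i, b in enumerate(model.hidden_b)},
    )


def load_nfm(path, expect_vocab_hash: str | None = None) -> NFMModel:
    z = np.load(path, allow_pickle=False)
    if int(z["version"]) != CHECKPOINT_VERSION:
        raise NFMError(f"unsupported checkpoint version {z['version']}")
    if expect_vocab_hash is not None and str(z["vocab_hash"]) != expect_vocab_hash:
        raise NFMError("checkpoint vocabulary hash does not match current inputs")
    cfg = NFMConfig(
        latent_dim=int(z["latent_dim"]),
        hidden_layers=int(z["hidden_layers"]),
        hidden_units=int(z["hidden_units"]),
        lr=float(z["lr"]),
        epochs=int(z["epochs"]),
        batch_size=int(z["batch_size"]),
        seed=int(z["seed"]),
    )
    model = NFMModel(
        w0=ag.Tensor(z["w0"], requires_grad=True),
        w=ag.Tensor(z["w"], requires_grad=True),
        V=ag.Tensor(z["V"], requires_grad=True),
        hidden_W=[ag.Tensor(z[f"hW{i}"], requires_grad=True) for i in range(int(z["hidden_layers"]))],
        hidden_b=[ag.Tensor(z[f"hb{i}"], requires_grad=True) for i in range(int(z["hidden_layers"]))],
        p=ag.Tensor(z["p"], requires_grad=True),
        cfg=cfg,
    )
    return model
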