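"""Training, evaluation and checkpointing of the visit-sequence generator."""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..cohort import TokenizedCohort
from .network import CausalVisitTransformer, bce_with_logits


@dataclass
class EngineConfig:
    """Desk-scale defaults: 2 layers, 4 heads, 64-dim embeddings.

    Larger production-style presets (4-12 layers, 256-768 dims) are
    reachable through the same fields.
    """

    n_layers: int = 2
    embedding_dim: int = 64
    n_heads: int = 4
    batch_size: int = 16
    max_sequence_length: int = 16   # max_visits + 3 special positions
    learning_rate: float = 1.5e-3
    epochs: int = 20
    seed: int = 0
    patience: int = 5
    grad_clip: float = 1.0
    ema_decay: float = 0.995        # Polyak weight averaging (0 disables)
    within_visit: bool = True       # within-visit autoregressive token head
    mixed_precision: bool = False   # float32 throughout; flag kept for parity

    def __post_init__(self):
        if self.embedding_dim % self.n_heads:
            raise ValueError("embedding_dim must be divisible by n_heads")
        if self.max_sequence_length < 2:
            raise ValueError("max_sequence_length must be >= 2")


@dataclass
class GeneratorModel:
    config: EngineConfig
    vocab_fingerprint: str
    net: CausalVisitTransformer
    train_history: list = field(default_factory=list)
    best_val_loss: float = float("nan")

    def check_vocab(self, vocab) -> None:
        if vocab.fingerprint() != self.vocab_fingerprint:
            raise ValueError(
                "vocabulary fingerprint mismatch: the cohort was tokenized "
                "with a different vocabulary than this model was trained on"
            )


def dense_sequences(tok: TokenizedCohort, max_len: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pack a tokenized cohort into (X, mask).

    Layout per patient: position 0 start-of-record vector, position 1 the
    static/label vector, positions 2..k+1 the visit vectors, position k+2 an
    end-of-record vector.  ``mask[b, t]`` marks positions whose *next*
    vector is a prediction target.
    """
    vocab = tok.vocab
    V = len(vocab)
    B = len(tok.patients)
    X = np.zeros((B, max_len, V), np.float32)
    mask = np.zeros((B, max_len), np.float32)
    for b, tp in enumerate(tok.patients):
        k = min(len(tp.visits), max_len - 3)
        X[b, 0, vocab.sor] = 1.0
        X[b, 1, tp.label] = 1.0
        for j in range(k):
            X[b, 2 + j, tp.visits[j]] = 1.0
        X[b, 2 + k, vocab.eor] = 1.0
        mask[b, 0 : 2 + k] = 1.0  # targets: label, visits..., eor
    return X, mask


def inputs_with_context(X: np.ndarray) -> np.ndarray:
    """Model inputs with the static/label vector carried into every visit
    position, so demographics condition each step directly (targets are
    untouched)."""
    Xin = X.copy()
    Xin[:, 2:] = np.clip(Xin[:, 2:] + X[:, 1:2], 0.0, 1.0)
    return Xin


def evaluate_loss(net: CausalVisitTransformer, X: np.ndarray, mask: np.ndarray,
                  batch_size: int = 256) -> float:
    total, n = 0.0, 0
    Wm = net.win_matrix()
    Xin = inputs_with_context(X)
    for s in range(0, len(X), batch_size):
        xb, mb = X[s : s + batch_size], mask[s : s + batch_size, : X.shape[1] - 1]
        y = xb[:, 1:]
        z = net.forward(Xin[s : s + batch_size, :-1])
        if Wm is not None:
            z = z + y @ Wm
        m = mb.astype(bool)
        per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
        total += float(per[m].sum())
        n += int(m.sum())
    if n == 0:
        raise ValueError("empty evaluation set")
    return total / n


def train_engine(tokenized_train: TokenizedCohort,
                 tokenized_val: Optional[TokenizedCohort],
                 config: EngineConfig) -> GeneratorModel:
    """Fit the generator with Adam, early-stopping on validation loss.

    Deterministic for a fixed seed and thread configuration; aborts with
    diagnostics on a non-finite loss.
    """
    if len(tokenized_train) == 0:
        raise ValueError("empty training set")
    if tokenized_val is not None and tokenized_val.vocab.fingerprint() \
            != tokenized_train.vocab.fingerprint():
        raise ValueError("train/validation vocabulary mismatch")
    V = len(tokenized_train.vocab)
    T = config.max_sequence_length
    Xtr, Mtr = dense_sequences(tokenized_train, T)
    Xtr_in = inputs_with_context(Xtr)
    has_val = tokenized_val is not None and len(tokenized_val) > 0
    if has_val:
        Xva, Mva = dense_sequences(tokenized_val, T)

    net = CausalVisitTransformer(V, config.embedding_dim, config.n_heads,
                                 config.n_layers, T, seed=config.seed,
                                 within_visit=config.within_visit)
    vocab = tokenized_train.vocab
    net.set_win_groups(list(vocab.static_groups().values())
                       + list(vocab.visit_groups().values()))
    # anchor the output bias at the empirical visit-vector marginals so the
    # sampler starts calibrated where most positions live; positional
    # embeddings learn the label/end-of-record corrections
    targets = Xtr[:, 1:][Mtr[:, : T - 1].astype(bool)]
    visit_rows = targets[:, vocab.eov] > 0
    marg = targets[visit_rows].mean(0) if visit_rows.any() else targets.mean(0)
    marg = np.clip(marg, 1e-4, 1 - 1e-4)
    net.params["out_b"] = np.log(marg / (1 - marg)).astype(np.float32)
    rng = np.random.default_rng(config.seed + 1)
    m_adam = {k: np.zeros_like(v) for k, v in net.params.items()}
    v_adam = {k: np.zeros_like(v) for k, v in net.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = []
    # exponentially averaged weights smooth minibatch noise; validation and
    # checkpoint selection both use the averaged parameters
    ema = {k: v.copy() for k, v in net.params.items()}
    ema_decay = config.ema_decay
    best = (float("inf"), copy.deepcopy(ema))
    stall = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        ep_loss, nb = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s : s + config.batch_size]
            xb = Xtr[idx]
            mb = Mtr[idx, : T - 1]
            logits, cache = net.forward(Xtr_in[idx][:, :-1], need_cache=True)
            teacher = xb[:, 1:]
            Wm = net.win_matrix()
            if Wm is not None:
                logits = logits + teacher @ Wm
            loss, dz = bce_with_logits(logits, teacher, mb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {step}: {loss}"
                )
            grads = net.backward(cache, dz)
            if Wm is not None:
                grads["win"] = net.win_grad(teacher, dz)
            gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            scale = min(1.0, config.grad_clip / (gnorm + 1e-12))
            step += 1
            lr = config.learning_rate
            for k2, gval in grads.items():
                gval = gval * scale
                m_adam[k2] = beta1 * m_adam[k2] + (1 - beta1) * gval
                v_adam[k2] = beta2 * v_adam[k2] + (1 - beta2) * gval**2
                mhat = m_adam[k2] / (1 - beta1**step)
                vhat = v_adam[k2] / (1 - beta2**step)
                net.params[k2] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)
            if ema_decay > 0:
                d = min(ema_decay, (1 + step) / (10 + step))
                for k2 in ema:
                    ema[k2] = d * ema[k2] + (1 - d) * net.params[k2]
            ep_loss += loss
            nb += 1
        eval_params = ema if ema_decay > 0 else net.params
        raw_params = net.params
        net.params = eval_params
        val = evaluate_loss(net, Xva, Mva) if has_val else ep_loss / max(nb, 1)
        net.params = raw_params
        history.append({"epoch": epoch, "train_loss": ep_loss / max(nb, 1),
                        "val_loss": val})
        if val < best[0] - 1e-6:
            best = (val, copy.deepcopy(eval_params))
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    net.params = best[1]
    return GeneratorModel(
        config=config,
        vocab_fingerprint=tokenized_train.vocab.fingerprint(),
        net=net,
        train_history=history,
        best_val_loss=best[0],
    )


def perplexity_proxy(model: GeneratorModel, tokenized_test: TokenizedCohort) -> float:
    """Mean per-position summed binary cross-entropy on held-out data."""
    model.check_vocab(tokenized_test.vocab)
    if len(tokenized_test) == 0:
        raise ValueError("empty test set")
    X, M = dense_sequences(tokenized_test, model.config.max_sequence_length)
    return evaluate_loss(model.net, X, M)


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(model: GeneratorModel, path) -> None:
    import dataclasses

    header = {
        "format": "ehrsynth-engine-v1",
        "config": dataclasses.asdict(model.config),
        "vocab_fingerprint": model.vocab_fingerprint,
        "best_val_loss": model.best_val_loss,
        "history": model.train_history,
        "net": {"V": model.net.V, "D": model.net.D, "H": model.net.H,
                "L": model.net.L, "max_len": model.net.max_len,
                "within_visit": model.net.within_visit,
                "win_groups": model.net._win_groups},
    }
    np.savez_compressed(path, __header__=json.dumps(header),
                        **model.net.params)


def load_checkpoint(path) -> GeneratorModel:
    data = np.load(path, allow_pickle=False)
    header = json.loads(str(data["__header__"]))
    if header.get("format") != "ehrsynth-engine-v1":
        raise ValueError("not an ehrsynth engine checkpoint")
    cfg = EngineConfig(**header["config"])
    nd = header["net"]
    net = CausalVisitTransformer(nd["V"], nd["D"], nd["H"], nd["L"], nd["max_len"],
                                 within_visit=nd.get("within_visit", True))
    net.set_win_groups(nd.get("win_groups", []))
    net.params = {k: data[k] for k in net.params}
    return GeneratorModel(cfg, header["vocab_fingerprint"], net,
                          header.get("history", []),
                          header.get("best_val_loss", float("nan")))
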