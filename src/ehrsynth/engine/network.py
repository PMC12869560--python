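"""A small causal transformer over visit positions, in pure numpy.

Each sequence position holds a multi-hot token vector (one visit, or the
label/special vector); the model predicts the next position's Bernoulli
probabilities for every token.  Pre-layer-norm blocks, learned positional
embeddings, GELU feed-forward, causal masks generated at runtime for the
actual sequence length, and raw-logit outputs for a numerically stable
binary cross-entropy.  Forward and backward passes are hand-written; the
Adam update lives in :mod:`ehrsynth.engine.model`.
"""

from __future__ import annotations

import math

import numpy as np

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)
_LN_EPS = 1e-5


def _gelu(x):
    inner = _SQRT_2_OVER_PI * (x + 0.044715 * x**3)
    return 0.5 * x * (1.0 + np.tanh(inner))


def _gelu_grad(x):
    inner = _SQRT_2_OVER_PI * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * _SQRT_2_OVER_PI * (
        1.0 + 3 * 0.044715 * x**2
    )


def _ln_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv)


def _ln_backward(dy, cache, g):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


class CausalVisitTransformer:
    """Parameters as a dict of float32 arrays; explicit forward/backward."""

    def __init__(self, vocab_size: int, d_model: int, n_heads: int,
                 n_layers: int, max_len: int, seed: int = 0,
                 within_visit: bool = True):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.V, self.D, self.H, self.L = vocab_size, d_model, n_heads, n_layers
        self.Dh = d_model // n_heads
        self.max_len = max_len
        self.within_visit = within_visit
        # token j may inform the logit of token i only when j < i
        self._win_mask = np.triu(np.ones((vocab_size, vocab_size), np.float32), 1)
        self._win_groups: list[list[int]] = []
        rng = np.random.default_rng(seed)

        def init(*shape, scale=0.02):
            return (scale * rng.standard_normal(shape)).astype(np.float32)

        p = {
            "emb": init(vocab_size, d_model),
            "pos": init(max_len, d_model, scale=0.01),
            "lnf_g": np.ones(d_model, np.float32),
            "lnf_b": np.zeros(d_model, np.float32),
            "out_w": init(d_model, vocab_size),
            "out_b": np.zeros(vocab_size, np.float32),
        }
        if within_visit:
            # within-visit autoregressive head over the token order; starts
            # at zero so the model begins as conditionally independent
            p["win"] = np.zeros((vocab_size, vocab_size), np.float32)
        res_scale = 0.02 / math.sqrt(2 * n_layers)
        for i in range(n_layers):
            p[f"l{i}.ln1_g"] = np.ones(d_model, np.float32)
            p[f"l{i}.ln1_b"] = np.zeros(d_model, np.float32)
            p[f"l{i}.wq"] = init(d_model, d_model)
            p[f"l{i}.wk"] = init(d_model, d_model)
            p[f"l{i}.wv"] = init(d_model, d_model)
            p[f"l{i}.wo"] = init(d_model, d_model, scale=res_scale)
            p[f"l{i}.ln2_g"] = np.ones(d_model, np.float32)
            p[f"l{i}.ln2_b"] = np.zeros(d_model, np.float32)
            p[f"l{i}.w1"] = init(d_model, 4 * d_model)
            p[f"l{i}.b1"] = np.zeros(4 * d_model, np.float32)
            p[f"l{i}.w2"] = init(4 * d_model, d_model, scale=res_scale)
            p[f"l{i}.b2"] = np.zeros(d_model, np.float32)
        self.params = p

    # -- forward -----------------------------------------------------------
    def forward(self, X: np.ndarray, need_cache: bool = False):
        """X: (B, T, V) multi-hot float32.  Returns logits (B, T, V)."""
        p = self.params
        B, T, V = X.shape
        if T > self.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.max_len}")
        # causal mask built at runtime for this T
        neg = np.full((T, T), -1e9, np.float32)
        causal = np.triu(neg, k=1)[None, None]  # (1,1,T,T)

        h = X @ p["emb"] + p["pos"][:T]
        cache = {"X": X, "T": T, "layers": []}
        for i in range(self.L):
            lc = {}
            a, lc["ln1"] = _ln_forward(h, p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"])
            lc["a"] = a
            q = a @ p[f"l{i}.wq"]
            k = a @ p[f"l{i}.wk"]
            v = a @ p[f"l{i}.wv"]

            def split(x):  # (B,T,D) -> (B,H,T,Dh)
                return x.reshape(B, T, self.H, self.Dh).transpose(0, 2, 1, 3)

            qh, kh, vh = split(q), split(k), split(v)
            scores = qh @ kh.transpose(0, 1, 3, 2) / math.sqrt(self.Dh) + causal
            scores -= scores.max(-1, keepdims=True)
            e = np.exp(scores)
            att = e / e.sum(-1, keepdims=True)
            oh = att @ vh
            o = oh.transpose(0, 2, 1, 3).reshape(B, T, self.D)
            attn_out = o @ p[f"l{i}.wo"]
            lc.update(qh=qh, kh=kh, vh=vh, att=att, o=o)
            h = h + attn_out

            m, lc["ln2"] = _ln_forward(h, p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])
            lc["m"] = m
            z1 = m @ p[f"l{i}.w1"] + p[f"l{i}.b1"]
            ff = _gelu(z1) @ p[f"l{i}.w2"] + p[f"l{i}.b2"]
            lc["z1"] = z1
            h = h + ff
            cache["layers"].append(lc)

        hf, cache["lnf"] = _ln_forward(h, p["lnf_g"], p["lnf_b"])
        cache["hf"] = hf
        logits = hf @ p["out_w"] + p["out_b"]
        return (logits, cache) if need_cache else logits

    def set_win_groups(self, groups) -> None:
        """Zero within-visit coupling inside mutually exclusive token groups
        (one-level-per-variable structure is enforced by the sampler, so the
        head should not spend capacity on it and group probabilities stay
        marginally calibrated)."""
        self._win_groups = [sorted(int(i) for i in g) for g in groups]
        self._win_mask = np.triu(
            np.ones((self.V, self.V), np.float32), 1)
        for g in self._win_groups:
            idx = np.asarray(g)
            self._win_mask[np.ix_(idx, idx)] = 0.0

    def win_matrix(self):
        """Masked within-visit coupling matrix (None when disabled)."""
        if not self.within_visit or "win" not in self.params:
            return None
        return self.params["win"] * self._win_mask

    def win_grad(self, teacher: np.ndarray, dlogits: np.ndarray) -> np.ndarray:
        V = self.V
        g = teacher.reshape(-1, V).T @ dlogits.reshape(-1, V)
        return g * self._win_mask

    # -- backward ----------------------------------------------------------
    def backward(self, cache, dlogits):
        p = self.params
        B, T = dlogits.shape[:2]
        g = {}
        hf = cache["hf"]
        g["out_w"] = hf.reshape(-1, self.D).T @ dlogits.reshape(-1, self.V)
        g["out_b"] = dlogits.sum((0, 1))
        dhf = dlogits @ p["out_w"].T
        dh, g["lnf_g"], g["lnf_b"] = _ln_backward(dhf, cache["lnf"], p["lnf_g"])

        for i in reversed(range(self.L)):
            lc = cache["layers"][i]
            # feed-forward
            dff = dh
            gelu_z1 = _gelu(lc["z1"])
            g[f"l{i}.w2"] = gelu_z1.reshape(-1, 4 * self.D).T @ dff.reshape(-1, self.D)
            g[f"l{i}.b2"] = dff.sum((0, 1))
            dz1 = (dff @ p[f"l{i}.w2"].T) * _gelu_grad(lc["z1"])
            g[f"l{i}.w1"] = lc["m"].reshape(-1, self.D).T @ dz1.reshape(-1, 4 * self.D)
            g[f"l{i}.b1"] = dz1.sum((0, 1))
            dm = dz1 @ p[f"l{i}.w1"].T
            dh2, g[f"l{i}.ln2_g"], g[f"l{i}.ln2_b"] = _ln_backward(
                dm, lc["ln2"], p[f"l{i}.ln2_g"]
            )
            dh = dh + dh2

            # attention
            dattn = dh
            g[f"l{i}.wo"] = lc["o"].reshape(-1, self.D).T @ dattn.reshape(-1, self.D)
            do = (dattn @ p[f"l{i}.wo"].T).reshape(B, T, self.H, self.Dh)
            doh = do.transpose(0, 2, 1, 3)
            datt = doh @ lc["vh"].transpose(0, 1, 3, 2)
            dvh = lc["att"].transpose(0, 1, 3, 2) @ doh
            att = lc["att"]
            dscores = att * (datt - (datt * att).sum(-1, keepdims=True))
            dscores /= math.sqrt(self.Dh)
            dqh = dscores @ lc["kh"]
            dkh = dscores.transpose(0, 1, 3, 2) @ lc["qh"]

            def merge(x):  # (B,H,T,Dh) -> (B,T,D)
                return x.transpose(0, 2, 1, 3).reshape(B, T, self.D)

            dq, dk, dv = merge(dqh), merge(dkh), merge(dvh)
            a2 = lc["a"].reshape(-1, self.D)
            g[f"l{i}.wq"] = a2.T @ dq.reshape(-1, self.D)
            g[f"l{i}.wk"] = a2.T @ dk.reshape(-1, self.D)
            g[f"l{i}.wv"] = a2.T @ dv.reshape(-1, self.D)
            da = dq @ p[f"l{i}.wq"].T + dk @ p[f"l{i}.wk"].T + dv @ p[f"l{i}.wv"].T
            dh1, g[f"l{i}.ln1_g"], g[f"l{i}.ln1_b"] = _ln_backward(
                da, lc["ln1"], p[f"l{i}.ln1_g"]
            )
            dh = dh + dh1

        X = cache["X"]
        g["emb"] = X.reshape(-1, self.V).T @ dh.reshape(-1, self.D)
        g["pos"] = np.zeros_like(p["pos"])
        g["pos"][:T] = dh.sum(0)
        return g


def bce_with_logits(logits, targets, mask):
    """Mean over masked positions of the per-position *summed* BCE.

    ``mask`` (B, T) selects target positions.  Returns (loss, dlogits);
    dlogits already includes the 1/n_masked normalization.
    """
    m = mask.astype(bool)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty mask")
    z, y = logits, targets
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float(per[m].sum() / n)
    dz = np.zeros_like(z)
    sig = 1.0 / (1.0 + np.exp(-z[m]))
    dz[m] = (sig - y[m]) / n
    return loss, dz
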