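"""Spatial encoder and stacked bidirectional recurrent classifier.

The encoder is a configurable convolutional stack (standard conv/pool
arithmetic ``out = floor((H + 2K - U)/D) + 1``; "same" padding means
``K = (U-1)/2``), with the per-keyframe embedding read from the penultimate
fully-connected layer.  The desk-scale default is a small fixed-weight
(seeded random projection) encoder; the full 152-layer residual schedule is
expressible as an :class:`EncoderConfig` for larger runs but is not trained
here.

The sequence classifier stacks two bidirectional LSTM layers; the final
forward and backward hidden states are spliced, concatenated with the
mean-pooled fused-feature summary, projected to two classes and softmaxed.
Training is mini-batch stochastic gradient descent with momentum on the
softmax cross-entropy, with analytic backpropagation-through-time gradients
(numerically verified in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import LABELS


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# encoder configuration and arithmetic
# ---------------------------------------------------------------------------

def conv_out_size(size: int, kernel: int, stride: int, padding) -> int:
    """Spatial output size of a conv/pool layer."""
    if padding == "same":
        if kernel % 2 == 0:
            raise ConfigError("'same' padding requires an odd kernel")
        padding = (kernel - 1) // 2
    out = (size + 2 * padding - kernel) // stride + 1
    return out


@dataclass
class EncoderConfig:
    """Layer schedule of the spatial encoder.

    ``layers`` is a list of tuples:
      ("conv", out_channels, kernel, stride, padding)  padding: int | "same"
      ("pool", kernel, stride)
      ("fc", size)
    The embedding is the output of the penultimate fully-connected layer.
    """

    input_size: tuple[int, int, int] = (32, 32, 3)  # H, W, C
    layers: list = field(default_factory=lambda: [
        ("conv", 6, 3, 2, "same"),
        ("pool", 2, 2),
        ("conv", 12, 3, 2, "same"),
        ("fc", 8),
        ("fc", 2),
    ])

    def shape_table(self) -> list[tuple[int, int, int]]:
        """Per-layer (H, W, C) output shapes; raises on degenerate layers."""
        h, w, c = self.input_size
        shapes = []
        for idx, spec in enumerate(self.layers):
            kind = spec[0]
            if kind == "conv":
                _, out_c, u, d, k = spec
                h, w = conv_out_size(h, u, d, k), conv_out_size(w, u, d, k)
                c = out_c
            elif kind == "pool":
                _, u, d = spec
                h, w = conv_out_size(h, u, d, 0), conv_out_size(w, u, d, 0)
            elif kind == "fc":
                h, w, c = 1, 1, spec[1]
            else:
                raise ConfigError(f"unknown layer kind {kind!r}")
            if min(h, w, c) <= 0:
                raise ConfigError(
                    f"layer {idx} ({kind}) yields non-positive size {(h, w, c)}")
            shapes.append((h, w, c))
        return shapes

    @property
    def embedding_dim(self) -> int:
        fc = [s for s, l in zip(self.shape_table(), self.layers) if l[0] == "fc"]
        if len(fc) < 2:
            raise ConfigError("need at least two fully-connected layers")
        return fc[-2][2]


def resnet152_encoder_config(input_size=(224, 224, 3)) -> EncoderConfig:
    """The 152-layer residual schedule flattened into an EncoderConfig.

    Residual/skip semantics are not represented — this is the layer
    bookkeeping (conv7-64, 3/8/36/3 bottleneck stages, head) for users who
    want to attach a GPU-scale encoder; desk runs use the small default.
    """
    layers: list = [("conv", 64, 7, 2, "same"), ("pool", 3, 2)]
    stages = [(3, 64, 256), (8, 128, 512), (36, 256, 1024), (3, 512, 2048)]
    for repeat, mid, out in stages:
        for _ in range(repeat):
            layers += [("conv", mid, 1, 1, 0),
                       ("conv", mid, 3, 1, "same"),
                       ("conv", out, 1, 1, 0)]
        layers.append(("pool", 2, 2))
    layers += [("fc", 1000), ("fc", 2)]
    return EncoderConfig(input_size=input_size, layers=layers)


# ---------------------------------------------------------------------------
# encoder forward pass
# ---------------------------------------------------------------------------

def _relu(x):
    return np.maximum(x, 0.0)


def _conv2d(x, w, b, stride, padding):
    """x (B, H, W, Cin), w (U, U, Cin, Cout) -> (B, Ho, Wo, Cout)."""
    u = w.shape[0]
    if padding == "same":
        padding = (u - 1) // 2
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    B, H, W, _ = x.shape
    ho = (H - u) // stride + 1
    wo = (W - u) // stride + 1
    out = np.zeros((B, ho, wo, w.shape[3]))
    for du in range(u):
        for dv in range(u):
            patch = x[:, du:du + stride * ho:stride, dv:dv + stride * wo:stride]
            out += patch @ w[du, dv]
    return out + b


def _maxpool2d(x, kernel, stride):
    B, H, W, C = x.shape
    ho = (H - kernel) // stride + 1
    wo = (W - kernel) // stride + 1
    out = np.full((B, ho, wo, C), -np.inf)
    for du in range(kernel):
        for dv in range(kernel):
            patch = x[:, du:du + stride * ho:stride, dv:dv + stride * wo:stride]
            np.maximum(out, patch, out=out)
    return out


class Encoder:
    """Fixed-weight spatial encoder (seeded He-initialised random projection)."""

    def __init__(self, config: EncoderConfig | None = None, seed: int = 0):
        self.config = config or EncoderConfig()
        self.config.shape_table()  # validate
        rng = np.random.default_rng(seed)
        self.weights = []
        h, w, c = self.config.input_size
        flat = None
        for spec in self.config.layers:
            if spec[0] == "conv":
                _, out_c, u, d, k = spec
                fan_in = u * u * c
                wt = rng.normal(0, np.sqrt(2.0 / fan_in), (u, u, c, out_c))
                self.weights.append((wt, np.zeros(out_c)))
                h, w = conv_out_size(h, u, d, k), conv_out_size(w, u, d, k)
                c = out_c
            elif spec[0] == "pool":
                _, u, d = spec
                self.weights.append(None)
                h, w = conv_out_size(h, u, d, 0), conv_out_size(w, u, d, 0)
            else:
                size = spec[1]
                if flat is None:
                    flat = h * w * c
                wt = rng.normal(0, np.sqrt(2.0 / flat), (flat, size))
                self.weights.append((wt, np.zeros(size)))
                flat = size

    def forward(self, frames: np.ndarray) -> np.ndarray:
        """Per-keyframe embeddings from a (B, H, W, 3) uint8/float batch."""
        x = np.asarray(frames, dtype=float) / 255.0 - 0.5
        if x.ndim == 3:
            x = x[None]
        expect = self.config.input_size
        if x.shape[1:] != expect:
            raise ConfigError(
                f"frames of shape {x.shape[1:]} do not match encoder input "
                f"{expect}; resize first")
        embedding = None
        flat = None
        fc_seen = 0
        n_fc = sum(1 for l in self.config.layers if l[0] == "fc")
        for spec, wts in zip(self.config.layers, self.weights):
            if spec[0] == "conv":
                x = _relu(_conv2d(x, wts[0], wts[1], spec[3], spec[4]))
            elif spec[0] == "pool":
                x = _maxpool2d(x, spec[1], spec[2])
            else:
                if flat is None:
                    x = x.reshape(len(x), -1)
                    flat = True
                x = x @ wts[0] + wts[1]
                fc_seen += 1
                if fc_seen < n_fc:
                    x = _relu(x)
                if fc_seen == n_fc - 1:
                    embedding = x
        return embedding


def encoder_forward(encoder: Encoder, frames: np.ndarray) -> np.ndarray:
    return encoder.forward(frames)


def resize_frames(frames: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Resize a (B, H, W, 3) stack to the encoder input size."""
    from skimage.transform import resize

    frames = np.asarray(frames)
    if frames.shape[1:3] == tuple(size):
        return frames
    out = np.stack([
        resize(f, size, preserve_range=True, anti_aliasing=True)
        for f in frames])
    return out


# ---------------------------------------------------------------------------
# sequence model (two stacked BLSTM layers + softmax head)
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean softmax cross-entropy; 0 for one-hot-correct, ln 2 for uniform."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-300, None)
    return float(-np.log(p).mean())


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _init_lstm(rng, d_in, hidden):
    s = 1.0 / np.sqrt(hidden)
    return {
        "Wx": rng.uniform(-s, s, (d_in, 4 * hidden)),
        "Wh": rng.uniform(-s, s, (hidden, 4 * hidden)),
        "b": np.zeros(4 * hidden),
    }


def _lstm_forward(X, mask, p, reverse):
    """Masked LSTM pass.  X (B,T,D), mask (B,T).  Returns per-step carried
    hidden states (B,T,H), the final hidden state, and the cache."""
    B, T, _ = X.shape
    H = p["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.zeros((B, T, H))
    cache = []
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        z = X[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        th = np.tanh(c_new)
        h_new = o * th
        m = mask[:, t][:, None]
        h_prev, c_prev = h, c
        h = m * h_new + (1 - m) * h
        c = m * c_new + (1 - m) * c
        hs[:, t] = h
        cache.append((t, h_prev, c_prev, i, f, g, o, c_new, th, m))
    return hs, h, cache


def _lstm_backward(X, p, cache, d_hs, d_h_final):
    """BPTT through one masked LSTM direction.

    d_hs: gradient w.r.t. the stored per-step states (may be zeros);
    d_h_final: gradient w.r.t. the final hidden state.
    Returns (dX, grads dict).
    """
    B, T, D = X.shape
    H = p["Wh"].shape[0]
    dX = np.zeros_like(X)
    g_Wx = np.zeros_like(p["Wx"])
    g_Wh = np.zeros_like(p["Wh"])
    g_b = np.zeros_like(p["b"])
    dh_carry = d_h_final.copy()
    dc_carry = np.zeros((B, H))
    for (t, h_prev, c_prev, i, f, g, o, c_new, th, m) in reversed(cache):
        dh = d_hs[:, t] + dh_carry
        dh_new = dh * m
        dh_prev = dh * (1 - m)
        dc_new = dc_carry * m + dh_new * o * (1 - th ** 2)
        dc_prev = dc_carry * (1 - m)
        do = dh_new * th
        df = dc_new * c_prev
        di = dc_new * g
        dg = dc_new * i
        dc_prev += dc_new * f
        dz = np.concatenate([
            di * i * (1 - i), df * f * (1 - f),
            dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
        g_Wx += X[:, t].T @ dz
        g_Wh += h_prev.T @ dz
        g_b += dz.sum(axis=0)
        dX[:, t] += dz @ p["Wx"].T
        dh_carry = dh_prev + dz @ p["Wh"].T
        dc_carry = dc_prev
    return dX, {"Wx": g_Wx, "Wh": g_Wh, "b": g_b}


@dataclass
class Hyperparams:
    """Training configuration for the sequence classifier."""

    hidden: int = 100
    batch_size: int = 32
    dropout: float = 0.2
    max_epochs: int = 64
    lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 5e-4
    gate_factor: float = 0.0   # key-feature threshold gate; 0 disables
    standardize: bool = True


class SequenceModel:
    """Two stacked BLSTM layers with a softmax classifier head."""

    def __init__(self, n_features: int, hyper: Hyperparams | None = None,
                 seed: int = 0):
        self.hyper = hyper or Hyperparams()
        self.n_features = n_features
        H = self.hyper.hidden
        rng = np.random.default_rng(seed)
        self.params = {
            "l1f": _init_lstm(rng, n_features, H),
            "l1b": _init_lstm(rng, n_features, H),
            "l2f": _init_lstm(rng, 2 * H, H),
            "l2b": _init_lstm(rng, 2 * H, H),
            "head_W": np.zeros((2 * H + n_features, 2)),
            "head_b": np.zeros(2),
        }
        self.feat_mean = np.zeros(n_features)
        self.feat_std = np.ones(n_features)

    # -- data plumbing ----------------------------------------------------

    def _pack(self, sequences):
        seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
        if any(s.shape[1] != self.n_features for s in seqs):
            raise ConfigError(
                f"sequence feature dimension does not match model "
                f"({self.n_features})")
        T = max(len(s) for s in seqs)
        B = len(seqs)
        X = np.zeros((B, T, self.n_features))
        mask = np.zeros((B, T))
        for k, s in enumerate(seqs):
            X[k, :len(s)] = (s - self.feat_mean) / self.feat_std
            mask[k, :len(s)] = 1.0
        if self.hyper.gate_factor > 0:
            X = threshold_gate(X, mask, self.hyper.gate_factor)
        return X, mask

    # -- forward ----------------------------------------------------------

    def _forward(self, X, mask, drop_rng=None):
        p = self.params
        keep = 1.0 - self.hyper.dropout if drop_rng is not None else 1.0
        hs1f, h1f, c1f = None, None, None
        hs1f, hf_fin, cache1f = _lstm_forward(X, mask, p["l1f"], reverse=False)
        hs1b, hb_fin, cache1b = _lstm_forward(X, mask, p["l1b"], reverse=True)
        Y1 = np.concatenate([hs1f, hs1b], axis=2)
        if drop_rng is not None and self.hyper.dropout > 0:
            dmask1 = (drop_rng.random(Y1.shape) < keep) / keep
            Y1 = Y1 * dmask1
        else:
            dmask1 = None
        hs2f, h2f_fin, cache2f = _lstm_forward(Y1, mask, p["l2f"], reverse=False)
        hs2b, h2b_fin, cache2b = _lstm_forward(Y1, mask, p["l2b"], reverse=True)
        rep = np.concatenate([h2f_fin, h2b_fin], axis=1)
        if drop_rng is not None and self.hyper.dropout > 0:
            dmask_r = (drop_rng.random(rep.shape) < keep) / keep
            rep = rep * dmask_r
        else:
            dmask_r = None
        denom = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
        pooled = (X * mask[..., None]).sum(axis=1) / denom
        full = np.concatenate([rep, pooled], axis=1)
        logits = full @ p["head_W"] + p["head_b"]
        probs = softmax(logits)
        cache = (X, mask, cache1f, cache1b, Y1, dmask1, cache2f, cache2b,
                 rep, dmask_r, pooled, full, probs)
        return probs, cache

    def _backward(self, cache, labels):
        (X, mask, cache1f, cache1b, Y1, dmask1, cache2f, cache2b,
         rep, dmask_r, pooled, full, probs) = cache
        p = self.params
        B = len(labels)
        H = self.hyper.hidden
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads = {"head_W": full.T @ dlogits, "head_b": dlogits.sum(axis=0)}
        dfull = dlogits @ p["head_W"].T
        drep = dfull[:, :2 * H]
        if dmask_r is not None:
            drep = drep * dmask_r
        zero_hs = np.zeros((B, Y1.shape[1], H))
        dY1_f, g2f = _lstm_backward(Y1, p["l2f"], cache2f, zero_hs,
                                    drep[:, :H])
        dY1_b, g2b = _lstm_backward(Y1, p["l2b"], cache2b, zero_hs,
                                    drep[:, H:])
        dY1 = dY1_f + dY1_b
        if dmask1 is not None:
            dY1 = dY1 * dmask1
        no_fin = np.zeros((B, H))
        _, g1f = _lstm_backward(X, p["l1f"], cache1f, dY1[:, :, :H], no_fin)
        _, g1b = _lstm_backward(X, p["l1b"], cache1b, dY1[:, :, H:], no_fin)
        grads["l1f"], grads["l1b"] = g1f, g1b
        grads["l2f"], grads["l2b"] = g2f, g2b
        return grads

    # -- public API -------------------------------------------------------

    def predict_proba(self, sequences) -> np.ndarray:
        """Class probabilities (TRUTH, LIE) per sequence; rows sum to 1."""
        X, mask = self._pack(sequences)
        probs, _ = self._forward(X, mask)
        return probs

    def predict(self, sequences) -> np.ndarray:
        return self.predict_proba(sequences).argmax(axis=1)

    def loss_and_grads(self, sequences, labels, drop_rng=None):
        X, mask = self._pack(sequences)
        probs, cache = self._forward(X, mask, drop_rng=drop_rng)
        loss = cross_entropy(probs, labels)
        grads = self._backward(cache, np.asarray(labels, dtype=int))
        return loss, grads


def threshold_gate(X: np.ndarray, mask: np.ndarray, factor: float) -> np.ndarray:
    """Key-feature gate: zero features whose mean absolute value over the
    sequence falls below ``factor`` times the sequence-wide mean."""
    denom = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
    per_feat = (np.abs(X) * mask[..., None]).sum(axis=1) / denom  # (B, D)
    cut = factor * per_feat.mean(axis=1, keepdims=True)
    keep = (per_feat >= cut).astype(float)
    return X * keep[:, None, :]


LABEL_TO_INT = {lab: i for i, lab in enumerate(LABELS)}  # TRUTH=0, LIE=1


def train_model(sequences, labels, hyper: Hyperparams | None = None,
                seed: int = 0):
    """Train the sequence classifier; returns (model, per-epoch loss trace).

    ``sequences`` is a list of (T_i, D) fused-feature arrays; ``labels``
    are LIE/TRUTH strings or {0, 1} integers (LIE positive).  Deterministic
    given the seed.
    """
    hyper = hyper or Hyperparams()
    labels = np.asarray([
        LABEL_TO_INT[l] if isinstance(l, str) else int(l) for l in labels])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    n_features = seqs[0].shape[1]
    model = SequenceModel(n_features, hyper, seed=seed)
    if hyper.standardize:
        stacked = np.vstack(seqs)
        model.feat_mean = stacked.mean(axis=0)
        std = stacked.std(axis=0)
        model.feat_std = np.where(std > 0, std, 1.0)

    rng = np.random.default_rng(seed + 1)
    velocity = _zeros_like_params(model.params)
    trace = []
    n = len(seqs)
    for _ in range(hyper.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        seen = 0
        for start in range(0, n, hyper.batch_size):
            idx = order[start:start + hyper.batch_size]
            batch = [seqs[i] for i in idx]
            loss, grads = model.loss_and_grads(batch, labels[idx],
                                               drop_rng=rng)
            epoch_loss += loss * len(idx)
            seen += len(idx)
            _sgd_step(model.params, grads, velocity, hyper)
        trace.append(epoch_loss / seen)
    return model, np.array(trace)


def _zeros_like_params(params):
    out = {}
    for k, v in params.items():
        out[k] = ({kk: np.zeros_like(vv) for kk, vv in v.items()}
                  if isinstance(v, dict) else np.zeros_like(v))
    return out


def _sgd_step(params, grads, velocity, hyper):
    def update(p, g, v):
        np.multiply(v, hyper.momentum, out=v)
        v -= hyper.lr * (g + hyper.weight_decay * p)
        p += v

    for k, v in params.items():
        if isinstance(v, dict):
            for kk in v:
                update(v[kk], grads[k][kk], velocity[k][kk])
        else:
            update(v, grads[k], velocity[k])
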