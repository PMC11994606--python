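"""Minimal NumPy neural-network toolkit used by the classifier and MIL model.

Everything here is plain NumPy with hand-derived backward passes: a 3x3
convolution via im2col, 2x2 max pooling, dense layers, a gated-attention
scorer, softmax cross-entropy and an Adam optimizer.  Networks are kept
deliberately small (tens of thousands of parameters) so that training on
synthetic slides runs in minutes on one CPU; gradient correctness is
enforced by finite-difference checks in the test suite.

Array convention: images are (N, H, W, C) float, features are (N, D).
Parameters live in flat ``{name: array}`` dicts so the optimizer and
checkpointing stay trivial.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits, target_idx, class_weights=None):
    """Mean weighted cross-entropy; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    wts = np.ones(n) if class_weights is None else np.asarray(class_weights)[target_idx]
    logp = np.log(np.clip(p[np.arange(n), target_idx], 1e-12, None))
    loss = -(wts * logp).sum() / wts.sum()
    dlogits = p * wts[:, None]
    dlogits[np.arange(n), target_idx] -= wts
    dlogits /= wts.sum()
    return float(loss), dlogits


# ---------------------------------------------------------------------------
# im2col convolution
# ---------------------------------------------------------------------------

def _im2col(x, kh, kw):
    """Sliding 'same'-padded kh x kw windows -> (N*OH*OW, kh*kw*C)."""
    n, h, w, c = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, shape=(n, h, w, kh, kw, c), strides=(s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return win.reshape(n * h * w, kh * kw * c)


def _col2im(dcol, x_shape, kh, kw):
    """Adjoint of :func:`_im2col` (accumulates overlapping windows)."""
    n, h, w, c = x_shape
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((n, h + 2 * ph, w + 2 * pw, c))
    dwin = dcol.reshape(n, h, w, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i:i + h, j:j + w, :] += dwin[:, :, :, i, j, :]
    return dxp[:, ph:ph + h, pw:pw + w, :]


class Conv3x3:
    """Same-padded 3x3 convolution, stride 1."""

    def __init__(self, c_in, c_out, rng, prefix):
        self.c_in, self.c_out, self.prefix = c_in, c_out, prefix
        scale = np.sqrt(2.0 / (9 * c_in))
        self.params = {
            f"{prefix}/W": rng.normal(0, scale, size=(9 * c_in, c_out)),
            f"{prefix}/b": np.zeros(c_out),
        }

    def forward(self, x, params):
        col = _im2col(x, 3, 3)
        y = col @ params[f"{self.prefix}/W"] + params[f"{self.prefix}/b"]
        n, h, w, _ = x.shape
        return y.reshape(n, h, w, self.c_out), (col, x.shape)

    def backward(self, dy, cache, params, grads):
        col, x_shape = cache
        dyf = dy.reshape(-1, self.c_out)
        grads[f"{self.prefix}/W"] = col.T @ dyf
        grads[f"{self.prefix}/b"] = dyf.sum(axis=0)
        dcol = dyf @ params[f"{self.prefix}/W"].T
        return _col2im(dcol, x_shape, 3, 3)


def maxpool2_forward(x):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(dy, cache):
    idx, (n, h, w, c) = cache
    dflat = np.zeros((n, h // 2, w // 2, c, 4))
    np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
    return (
        dflat.reshape(n, h // 2, w // 2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h, w, c)
    )


class Dense:
    def __init__(self, d_in, d_out, rng, prefix):
        self.prefix = prefix
        scale = np.sqrt(2.0 / d_in)
        self.params = {
            f"{prefix}/W": rng.normal(0, scale, size=(d_in, d_out)),
            f"{prefix}/b": np.zeros(d_out),
        }

    def forward(self, x, params):
        return x @ params[f"{self.prefix}/W"] + params[f"{self.prefix}/b"], x

    def backward(self, dy, cache, params, grads):
        x = cache
        grads[f"{self.prefix}/W"] = x.T @ dy
        grads[f"{self.prefix}/b"] = dy.sum(axis=0)
        return dy @ params[f"{self.prefix}/W"].T


# ---------------------------------------------------------------------------
# compact CNN: [conv-relu-pool] x 2 -> flatten -> dense
# ---------------------------------------------------------------------------

class SmallCNN:
    """Two conv-relu-pool stages over a downsampled patch, then a dense map.

    ``in_size`` must be divisible by 4; output is ``out_dim`` raw scores
    (squashing, if any, is the caller's business).
    """

    def __init__(self, in_size=32, channels=(8, 16), out_dim=2, seed=0, prefix="cnn"):
        if in_size % 4 != 0:
            raise ValueError("in_size must be divisible by 4")
        rng = np.random.default_rng(seed)
        self.in_size = in_size
        self.conv1 = Conv3x3(3, channels[0], rng, f"{prefix}/c1")
        self.conv2 = Conv3x3(channels[0], channels[1], rng, f"{prefix}/c2")
        self.fc = Dense((in_size // 4) ** 2 * channels[1], out_dim, rng, f"{prefix}/fc")
        self.params = {**self.conv1.params, **self.conv2.params, **self.fc.params}

    def forward(self, x, params=None):
        """x: (N, in_size, in_size, 3) in [0, 1]. Returns (out, cache)."""
        p = self.params if params is None else params
        if x.shape[1] != self.in_size or x.shape[2] != self.in_size:
            raise ValueError(
                f"expected {self.in_size}x{self.in_size} input, got {x.shape[1:3]}"
            )
        a1, c1 = self.conv1.forward(x, p)
        r1 = relu(a1)
        p1, cp1 = maxpool2_forward(r1)
        a2, c2 = self.conv2.forward(p1, p)
        r2 = relu(a2)
        p2, cp2 = maxpool2_forward(r2)
        flat = p2.reshape(x.shape[0], -1)
        out, cfc = self.fc.forward(flat, p)
        return out, (c1, a1, cp1, c2, a2, cp2, p2.shape, cfc)

    def backward(self, dout, cache, params=None):
        p = self.params if params is None else params
        c1, a1, cp1, c2, a2, cp2, p2shape, cfc = cache
        grads = {}
        dflat = self.fc.backward(dout, cfc, p, grads)
        dp2 = dflat.reshape(p2shape)
        dr2 = maxpool2_backward(dp2, cp2)
        da2 = dr2 * (a2 > 0)
        dp1 = self.conv2.backward(da2, c2, p, grads)
        dr1 = maxpool2_backward(dp1, cp1)
        da1 = dr1 * (a1 > 0)
        self.conv1.backward(da1, c1, p, grads)
        return grads


class MLP:
    """Dense-ReLU stack with a linear final layer; backward returns dx.

    ``final_zero`` zero-initializes the last layer so the stack starts
    as the constant-zero map — outputs (and the gradients flowing back
    through it) grow gently instead of starting from a large random
    transient.
    """

    def __init__(self, sizes, seed=0, prefix="mlp", final_zero=False):
        rng = np.random.default_rng(seed)
        self.layers = [
            Dense(a, b, rng, f"{prefix}/d{i}")
            for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:]))
        ]
        if final_zero:
            last = self.layers[-1]
            last.params[f"{last.prefix}/W"][:] = 0.0
        self.params = {}
        for l in self.layers:
            self.params.update(l.params)

    def forward(self, x, params=None):
        p = self.params if params is None else params
        caches, pre = [], []
        h = x
        for i, l in enumerate(self.layers):
            a, c = l.forward(h, p)
            caches.append(c)
            pre.append(a)
            h = relu(a) if i < len(self.layers) - 1 else a
        return h, (caches, pre)

    def backward(self, dout, cache, params=None):
        p = self.params if params is None else params
        caches, pre = cache
        grads = {}
        d = dout
        for i in reversed(range(len(self.layers))):
            if i < len(self.layers) - 1:
                d = d * (pre[i] > 0)
            d = self.layers[i].backward(d, caches[i], p, grads)
        return grads, d


class GatedAttention:
    """Gated attention scorer: a_i = w'(tanh(V f_i) * sigm(U f_i)).

    ``forward`` returns normalized (softmax over instances) weights.
    """

    def __init__(self, d_in, d_att=16, seed=0, prefix="att"):
        rng = np.random.default_rng(seed)
        s = np.sqrt(1.0 / d_in)
        self.prefix = prefix
        self.params = {
            f"{prefix}/V": rng.normal(0, s, size=(d_in, d_att)),
            f"{prefix}/bV": np.zeros(d_att),
            f"{prefix}/U": rng.normal(0, s, size=(d_in, d_att)),
            f"{prefix}/bU": np.zeros(d_att),
            f"{prefix}/w": rng.normal(0, np.sqrt(1.0 / d_att), size=(d_att, 1)),
            f"{prefix}/bw": np.zeros(1),
        }

    def forward(self, f, params=None):
        p = self.params if params is None else params
        pre = self.prefix
        t = np.tanh(f @ p[f"{pre}/V"] + p[f"{pre}/bV"])
        s = sigmoid(f @ p[f"{pre}/U"] + p[f"{pre}/bU"])
        g = t * s
        scores = (g @ p[f"{pre}/w"] + p[f"{pre}/bw"])[:, 0]
        w = softmax(scores)
        return w, (f, t, s, g, scores, w)

    def backward(self, dw, cache, params=None):
        p = self.params if params is None else params
        pre = self.prefix
        f, t, s, g, scores, w = cache
        # softmax over instances
        dscores = w * (dw - (dw * w).sum())
        grads = {
            f"{pre}/w": g.T @ dscores[:, None],
            f"{pre}/bw": np.array([dscores.sum()]),
        }
        dg = dscores[:, None] @ p[f"{pre}/w"].T
        dt = dg * s
        ds = dg * t
        dpre_t = dt * (1.0 - t**2)
        dpre_s = ds * s * (1.0 - s)
        grads[f"{pre}/V"] = f.T @ dpre_t
        grads[f"{pre}/bV"] = dpre_t.sum(axis=0)
        grads[f"{pre}/U"] = f.T @ dpre_s
        grads[f"{pre}/bU"] = dpre_s.sum(axis=0)
        df = dpre_t @ p[f"{pre}/V"].T + dpre_s @ p[f"{pre}/U"].T
        return grads, df


class Adam:
    """Adam optimizer over flat parameter dicts.

    ``clip_norm`` rescales each step's global gradient norm: single-bag
    steps occasionally produce outlier gradients that would otherwise
    saturate the squashed feature extractor for good.
    """

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, clip_norm=None):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params: dict, grads: dict) -> None:
        if self.clip_norm is not None:
            gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if gnorm > self.clip_norm:
                scale = self.clip_norm / gnorm
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def accumulate(total: dict, grads: dict) -> None:
    """In-place grad accumulation across bags/minibatches."""
    for k, g in grads.items():
        if k in total:
            total[k] = total[k] + g
        else:
            total[k] = g.copy()


def downsample(x: np.ndarray, out_size: int) -> np.ndarray:
    """Block-mean downsample (N, H, W, C) uint8/float to (N, out, out, C) in [0,1]."""
    n, h, w, c = x.shape
    if h % out_size or w % out_size:
        raise ValueError(f"extent {h}x{w} not divisible into {out_size} blocks")
    fy, fx = h // out_size, w // out_size
    xr = x.reshape(n, out_size, fy, out_size, fx, c).astype(float)
    return xr.mean(axis=(2, 4)) / 255.0
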