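"""Independent naive-loop oracles for the stage equations and metric
definitions, shared by the unit tests and the acceptance tests.

Everything here is written with explicit Python loops in float64, reading
only the layer weights — no code path is shared with the package's
vectorised implementations.
"""

import numpy as np

from ac4cpred.autodiff import Tensor
from ac4cpred.network import MHSABlock, SKCBlock, TCNStack


def naive_conv_same(x, w, b):
    """Per-element same-padded cross-correlation, float64."""
    c_out, c_in, k = w.shape
    n, _, length = x.shape
    half = (k - 1) // 2
    out = np.zeros((n, c_out, length))
    for s in range(n):
        for o in range(c_out):
            for t in range(length):
                acc = b[o]
                for c in range(c_in):
                    for i in range(k):
                        src = t - half + i
                        if 0 <= src < length:
                            acc += w[o, c, i] * x[s, c, src]
                out[s, o, t] = acc
    return out


def naive_batchnorm(u, gamma, beta, eps=1e-5):
    mu = u.mean(axis=(0, 2), keepdims=True)
    var = u.var(axis=(0, 2), keepdims=True)
    return (u - mu) / np.sqrt(var + eps) * gamma.reshape(1, -1, 1) \
        + beta.reshape(1, -1, 1)


def naive_skc(x, block: SKCBlock):
    """Split/fuse/select computed with explicit loops from the block's weights."""
    m = block.m
    branches = []
    for i in range(m):
        conv = getattr(block, f"conv{i}")
        norm = getattr(block, f"norm{i}")
        u = naive_conv_same(x, conv.w.data.astype(float), conv.b.data.astype(float))
        u = naive_batchnorm(u, norm.gamma.data.astype(float),
                            norm.beta.data.astype(float), norm.eps)
        branches.append(np.maximum(u, 0.0))
    fused = sum(branches)
    s = fused.mean(axis=2)  # GAP
    h = np.maximum(s @ block.fc1.w.data.astype(float) + block.fc1.b.data, 0.0)
    z = h @ block.fc2.w.data.astype(float) + block.fc2.b.data
    n, c = s.shape
    out = np.zeros_like(fused)
    weights = np.zeros((n, c, m))
    for sidx in range(n):
        for ch in range(c):
            logits = np.array([z[sidx, mi + m * ch] for mi in range(m)])
            e = np.exp(logits - logits.max())
            a = e / e.sum()
            weights[sidx, ch] = a
            for mi in range(m):
                out[sidx, ch] += a[mi] * branches[mi][sidx, ch]
    return out, weights


def naive_causal_dilated(xa, w, b, d):
    """Causal dilated convolution on (N, C, L): tap i reaches d*(k-1-i) back."""
    c_out, c_in, k = w.shape
    n, _, ln = xa.shape
    out = np.zeros((n, c_out, ln))
    for s in range(n):
        for o in range(c_out):
            for t in range(ln):
                acc = b[o]
                for c in range(c_in):
                    for i in range(k):
                        src = t - d * (k - 1 - i)
                        if src >= 0:
                            acc += w[o, c, i] * xa[s, c, src]
                out[s, o, t] = acc
    return out


def wn_kernel(conv):
    """Effective kernel of a weight-normalised convolution: g * v / ||v||."""
    v = conv.v.data.astype(float)
    g = conv.g.data.astype(float)
    return v * g / (np.sqrt((v ** 2).sum(axis=(1, 2), keepdims=True)) + 1e-12)


def naive_tcn_block(x, block):
    """One residual block in eval mode, from the block's weights."""
    xa = x.astype(float)
    d = block.conv1.dilation
    h = np.maximum(naive_causal_dilated(xa, wn_kernel(block.conv1),
                                        block.conv1.b.data, d), 0)
    h = np.maximum(naive_causal_dilated(h, wn_kernel(block.conv2),
                                        block.conv2.b.data, d), 0)
    if block.skip is not None:
        skip = naive_causal_dilated(xa, block.skip.w.data.astype(float),
                                    block.skip.b.data, 1)
    else:
        skip = xa
    return np.maximum(h + skip, 0)


def naive_mhsa(x_nld, block: MHSABlock):
    """Per-head loop over query/key/value projections and row softmax."""
    n_batch, n, d = x_nld.shape
    outs = []
    for i in range(block.p.heads):
        wq = getattr(block, f"wq{i}")
        wk = getattr(block, f"wk{i}")
        wv = getattr(block, f"wv{i}")
        head = np.zeros((n_batch, n, block.p.head_dim))
        for s in range(n_batch):
            q = x_nld[s] @ wq.w.data.astype(float) + wq.b.data
            k = x_nld[s] @ wk.w.data.astype(float) + wk.b.data
            v = x_nld[s] @ wv.w.data.astype(float) + wv.b.data
            logits = q @ k.T / np.sqrt(block.p.head_dim)
            for row in range(n):
                e = np.exp(logits[row] - logits[row].max())
                a = e / e.sum()
                head[s, row] = a @ v
        outs.append(head)
    return np.concatenate(outs, axis=-1)


def probe_receptive_field(stack: TCNStack, channels: int, length: int = 80
                          ) -> list[bool]:
    """Which input positions change the final output position when nudged.

    The stack's conv biases are lifted to +10 so every ReLU pre-activation
    stays positive under a small nudge: the stack is then locally affine and
    the probe reads off the exact tap reachability instead of being masked
    by inactive units.
    """
    stack.eval()
    for name, param in stack.named_parameters():
        if name.endswith(".b"):
            param.data[...] = 10.0
    rng = np.random.default_rng(0)
    x = rng.standard_normal((1, channels, length))
    base = stack(Tensor(x.astype(np.float32))).data
    t_out = length - 1
    changed = []
    for t_in in range(length):
        xp = x.copy()
        xp[0, :, t_in] += 0.5
        out = stack(Tensor(xp.astype(np.float32))).data
        delta = np.abs(out[0, :, t_out] - base[0, :, t_out])
        changed.append(bool(delta.max() > 1e-6))
    return changed


def pair_count_auc(y, s):
    """P(score_pos > score_neg) + 0.5*P(tie) by exhaustive pair counting."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def direct_point_metrics(tp, fp, tn, fn):
    """Sn/Sp/Acc/MCC written out verbatim."""
    import math

    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / (tp + fp + tn + fn)
    denom = math.sqrt((tp + fn) * (tn + fn) * (tp + fp) * (tn + fp))
    mcc = (tp * tn - fp * fn) / denom
    return sn, sp, acc, mcc


def trapezoid_area(points):
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return sum((xs[i + 1] - xs[i]) * (ys[i + 1] + ys[i]) / 2.0
               for i in range(len(xs) - 1))
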