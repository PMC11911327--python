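"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain nested loops over the defining
equations, deliberately sharing no code with the package's vectorized
implementations.
"""

import numpy as np


def conv3x3_relu_loops(X, kernel, bias, padding="valid"):
    """Direct nested-loop 3x3 convolution + ReLU on a 2D array."""
    if padding == "same":
        Xp = np.zeros((X.shape[0] + 2, X.shape[1] + 2))
        Xp[1:-1, 1:-1] = X
    else:
        Xp = np.asarray(X, dtype=float)
    H, W = Xp.shape[0] - 2, Xp.shape[1] - 2
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = bias
            for m in range(3):
                for n in range(3):
                    acc += kernel[m, n] * Xp[i + m, j + n]
            out[i, j] = max(0.0, acc)
    return out


def maxpool2x2_loops(X):
    H2, W2 = X.shape[0] // 2, X.shape[1] // 2
    out = np.zeros((H2, W2))
    for i in range(H2):
        for j in range(W2):
            out[i, j] = max(
                X[2 * i, 2 * j], X[2 * i, 2 * j + 1],
                X[2 * i + 1, 2 * j], X[2 * i + 1, 2 * j + 1],
            )
    return out


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def gru_step_loops(x_t, h_prev, Wr, Wz, Wh, br, bz, bh):
    """Scalar-loop GRU step on single vectors; W* are (units+feat, units)."""
    u = h_prev.shape[0]
    hx = np.concatenate([h_prev, x_t])
    r = np.zeros(u)
    z = np.zeros(u)
    for k in range(u):
        r[k] = _sig(sum(hx[i] * Wr[i, k] for i in range(hx.shape[0])) + br[k])
        z[k] = _sig(sum(hx[i] * Wz[i, k] for i in range(hx.shape[0])) + bz[k])
    rhx = np.concatenate([r * h_prev, x_t])
    h_cand = np.zeros(u)
    for k in range(u):
        h_cand[k] = np.tanh(sum(rhx[i] * Wh[i, k] for i in range(rhx.shape[0])) + bh[k])
    return (1.0 - z) * h_prev + z * h_cand


def gru_forward_loops(seq, Wr, Wz, Wh, br, bz, bh):
    u = Wr.shape[1]
    h = np.zeros(u)
    states = []
    for t in range(seq.shape[0]):
        h = gru_step_loops(seq[t], h, Wr, Wz, Wh, br, bz, bh)
        states.append(h)
    return np.stack(states)


def attention_pool_loops(H, W, b, v):
    """Additive attention via direct score/softmax/weighted-sum evaluation."""
    T = H.shape[0]
    e = np.array([float(v @ np.tanh(W.T @ H[t] + b)) for t in range(T)])
    w = np.exp(e - e.max())
    alpha = w / w.sum()
    context = np.zeros(H.shape[1])
    for t in range(T):
        context += alpha[t] * H[t]
    return context, alpha


def model_forward_chain(x, weights, config):
    """Stage-wise composition of the per-layer oracles for a single window."""
    t = weights.tensors
    # conv blocks: multi-channel conv = sum of single-channel 3x3 convs
    maps = [np.asarray(x[:, :, None] if x.ndim == 2 else x)]  # H x W x C
    feat = maps[0]
    for i in range(len(config.conv_filters)):
        Wk = t[f"conv{i}_W"]
        bk = t[f"conv{i}_b"]
        H, Wd, Cin = feat.shape
        Cout = Wk.shape[3]
        out = np.zeros((H, Wd, Cout))
        for co in range(Cout):
            acc = np.full((H, Wd), bk[co])
            for ci in range(Cin):
                # linear part of the conv (ReLU applied after channel sum)
                padded = np.zeros((H + 2, Wd + 2))
                padded[1:-1, 1:-1] = feat[:, :, ci]
                for a in range(H):
                    for bcol in range(Wd):
                        for m in range(3):
                            for n in range(3):
                                acc[a, bcol] += Wk[m, n, ci, co] * padded[a + m, bcol + n]
            out[:, :, co] = np.maximum(acc, 0.0)
        pooled = np.stack([maxpool2x2_loops(out[:, :, co]) for co in range(out.shape[2])], axis=2)
        feat = pooled
    Ht, Wt, Ct = feat.shape
    seq = feat.reshape(Ht, Wt * Ct)
    states = gru_forward_loops(
        seq, t["gru_Wr"], t["gru_Wz"], t["gru_Wh"], t["gru_br"], t["gru_bz"], t["gru_bh"]
    )
    context, _ = attention_pool_loops(states, t["att_W"], t["att_b"], t["att_v"])
    h = context
    for i in range(len(config.dense_units)):
        h = np.maximum(h @ t[f"dense{i}_W"] + t[f"dense{i}_b"], 0.0)
    return float((h @ t["out_W"] + t["out_b"])[0])


def rmse_loops(y_pred, y_meas):
    n = len(y_pred)
    acc = 0.0
    for i in range(n):
        acc += (y_pred[i] - y_meas[i]) ** 2
    return (acc / n) ** 0.5
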