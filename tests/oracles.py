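"""Independent brute-force oracles used to validate the implementation.

Everything here is written as literally as possible — explicit Python loops
over nodes, neighbors and score pairs — and stays independent of the code
paths it checks (no autodiff, no vectorized segment ops, no sklearn).
"""

from __future__ import annotations

import math

import numpy as np


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "identity":
        return x
    if name == "tanh":
        return np.tanh(x)
    raise ValueError(name)


def neighbors(edge_index: np.ndarray, i: int) -> list[int]:
    """j such that (i, j) is a directed edge entry."""
    return [int(j) for s, j in edge_index if s == i]


def mpnn_oracle(x, edge_index, params, activation="relu"):
    """Literal evaluation: h_i' = σ(W h_i + b + Σ_{j∈N(i)} MLP([h_i‖h_j]))."""
    W, b = params["W"].data, params["b"].data
    M1, bm1 = params["M1"].data, params["bm1"].data
    M2, bm2 = params["M2"].data, params["bm2"].data
    n = x.shape[0]
    out = np.zeros((n, W.shape[1]))
    for i in range(n):
        acc = W.T @ x[i] + b
        for j in neighbors(edge_index, i):
            pair = np.concatenate([x[i], x[j]])
            hidden = np.maximum(M1.T @ pair + bm1, 0.0)
            acc = acc + M2.T @ hidden + bm2
        out[i] = _act(activation, acc)
    return out


def gat_oracle(x, edge_index, params, n_heads, concat_heads, slope=0.2, activation="relu"):
    """Literal per-head attention: e_ij = LeakyReLU(aᵀ[Wh_i‖Wh_j]),
    α = softmax over N(i)∪{i}, h_i' = σ(Σ_j α_ij W h_j); heads concatenated
    or averaged. Returns (h', alpha dict {(i, j, head): α})."""
    W = params["W"].data
    a_src, a_dst = params["a_src"].data, params["a_dst"].data
    b = params["b"].data
    n = x.shape[0]
    dh = a_src.shape[1]
    head_outputs = []
    alphas = {}
    for h in range(n_heads):
        Wh = np.stack([W[:, h * dh : (h + 1) * dh].T @ x[i] for i in range(n)])
        out_h = np.zeros((n, dh))
        for i in range(n):
            nbrs = neighbors(edge_index, i) + [i]  # transient self-loop
            logits = []
            for j in nbrs:
                e = float(a_src[h] @ Wh[i] + a_dst[h] @ Wh[j])
                logits.append(e if e > 0 else slope * e)
            logits = np.asarray(logits)
            w = np.exp(logits - logits.max())
            alpha = w / w.sum()
            for j, al in zip(nbrs, alpha):
                alphas[(i, j, h)] = float(al)
            out_h[i] = sum(al * Wh[j] for j, al in zip(nbrs, alpha))
        head_outputs.append(out_h)
    if concat_heads:
        pre = np.concatenate(head_outputs, axis=1)
    else:
        pre = np.mean(head_outputs, axis=0)
    return _act(activation, pre + b), alphas


def sage_oracle(x, edge_index, params, activation="relu"):
    """Literal evaluation: h_i' = σ(W h_i + (1/|N(i)|) Σ_j W h_j + b)."""
    W, b = params["W"].data, params["b"].data
    n = x.shape[0]
    out = np.zeros((n, W.shape[1]))
    for i in range(n):
        acc = W.T @ x[i] + b
        nbrs = neighbors(edge_index, i)
        if nbrs:
            acc = acc + sum(W.T @ x[j] for j in nbrs) / len(nbrs)
        out[i] = _act(activation, acc)
    return out


def gcn_oracle(x, edge_index, params, activation="relu"):
    """Symmetric-normalized convolution with self-loops, literal loops."""
    W, b = params["W"].data, params["b"].data
    n = x.shape[0]
    deg = np.array([len(neighbors(edge_index, i)) + 1 for i in range(n)], dtype=float)
    out = np.zeros((n, W.shape[1]))
    for i in range(n):
        acc = np.zeros(W.shape[1])
        for j in neighbors(edge_index, i) + [i]:
            acc += (W.T @ x[j]) / math.sqrt(deg[i] * deg[j])
        out[i] = _act(activation, acc + b)
    return out


# --------------------------------------------------------------- metric oracles
def confusion_counts(y, pred):
    tp = sum(1 for a, b in zip(y, pred) if a == 1 and b == 1)
    tn = sum(1 for a, b in zip(y, pred) if a == 0 and b == 0)
    fp = sum(1 for a, b in zip(y, pred) if a == 0 and b == 1)
    fn = sum(1 for a, b in zip(y, pred) if a == 1 and b == 0)
    return tp, tn, fp, fn


def mcc_oracle(tp, tn, fp, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0


def auc_pairwise(y, s):
    """P(score_pos > score_neg) + ½·P(tie), by exhaustive pair enumeration."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def average_precision_oracle(y, s):
    """Step-interpolated area under precision–recall: Σ (R_k − R_{k−1})·P_k,
    descending unique thresholds, ties grouped."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    thresholds = sorted(set(s), reverse=True)
    n_pos = int(y.sum())
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        sel = s >= t
        tp = int(((y == 1) & sel).sum())
        precision = tp / int(sel.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap
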