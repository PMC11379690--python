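"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: explicit python loops and
scalar formulas only, so agreement is evidence, not tautology.
"""

import numpy as np


def nt_xent_oracle(z: np.ndarray, pairing: np.ndarray, tau: float) -> float:
    """Double loop over all ordered positive pairs, scalar cosine sums."""
    z = np.asarray(z, dtype=np.float64)
    zn = z / np.linalg.norm(z, axis=1, keepdims=True)
    n = len(z)
    total = 0.0
    for i in range(n):
        num = np.exp(np.dot(zn[i], zn[pairing[i]]) / tau)
        den = 0.0
        for k in range(n):
            if k != i:
                den += np.exp(np.dot(zn[i], zn[k]) / tau)
        total += -np.log(num / den)
    return total / n


def bce_oracle(logits: np.ndarray, flags: np.ndarray) -> float:
    """Scalar binary cross-entropy, averaged over tasks then batch."""
    logits = np.asarray(logits, dtype=np.float64)
    flags = np.asarray(flags, dtype=np.float64)
    n, k = logits.shape
    per_task = []
    for j in range(k):
        acc = 0.0
        for i in range(n):
            p = 1.0 / (1.0 + np.exp(-logits[i, j]))
            acc += -(flags[i, j] * np.log(p) + (1 - flags[i, j]) * np.log(1 - p))
        per_task.append(acc / n)
    return float(np.mean(per_task))


def confusion_oracle(preds, labels):
    """Counting loop -> (TP, FP, FN, TN)."""
    tp = fp = fn = tn = 0
    for p, y in zip(preds, labels):
        if p == 1 and y == 1:
            tp += 1
        elif p == 1 and y == 0:
            fp += 1
        elif p == 0 and y == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def kruskal_h_oracle(groups) -> float:
    """H = 12/(N(N+1)) * sum n_i R_i_bar^2 ... via the rank formula (no ties)."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(pooled)
    ranks = np.empty_like(pooled)
    ranks[order] = np.arange(1, len(pooled) + 1)
    n_total = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
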