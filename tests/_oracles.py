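"""Independent reference implementations used to cross-check the package."""

import itertools
import math

import numpy as np


def brute_force_entropy(W, mode):
    """Double-loop reference for share normalization and entropy."""
    K, S = W.shape
    P = np.zeros_like(W, dtype=float)
    for k in range(K):
        for s in range(S):
            if mode == "per_cell":
                tot = sum(W[k2][s] for k2 in range(K))
            else:
                tot = sum(W[k][s2] for s2 in range(S))
            P[k][s] = W[k][s] / tot if tot > 0 else 0.0
    E = np.zeros(K)
    for k in range(K):
        acc = 0.0
        for s in range(S):
            if P[k][s] > 0:
                acc -= P[k][s] * math.log(P[k][s])
        E[k] = acc
    return P, E


def mann_whitney_auc(scores, truth):
    """Exhaustive pair-counting AUC: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for g, s in scores.items() if g in truth]
    neg = [s for g, s in scores.items() if g not in truth]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))
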