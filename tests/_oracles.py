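"""Independent brute-force oracles for the statistical operations.

These deliberately use the most literal definition of each quantity
(pair counting, exhaustive threshold scans) rather than any closed form or
ranking shortcut, so they can certify the package implementations.
"""

from __future__ import annotations

import numpy as np


def auc_pair_counting(scores, labels) -> float:
    """AUC as explicit concordant-pair counting, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def youden_scan(scores, labels, direction: str) -> float:
    """Maximum Youden J over a dense exhaustive threshold scan."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    u = np.unique(scores)
    pad = 1.0 if len(u) == 1 else (u[-1] - u[0])
    cands = np.concatenate([[u[0] - pad], u, (u[:-1] + u[1:]) / 2.0, [u[-1] + pad]])
    best = -np.inf
    for c in cands:
        pred = scores <= c if direction == "below" else scores >= c
        tp = int(((labels == 1) & pred).sum())
        fn = int(((labels == 1) & ~pred).sum())
        tn = int(((labels == 0) & ~pred).sum())
        fp = int(((labels == 0) & pred).sum())
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        best = max(best, j)
    return best


def confusion_tables_matching(n_pos: int, n_neg: int,
                              ppv_pct: float | None = None,
                              npv_pct: float | None = None,
                              f1: float | None = None,
                              decimals: int = 2) -> list[tuple[int, int, int, int]]:
    """All integer confusion tables with the given class sizes whose printed
    (rounded) PPV/NPV/F1 match the stated values."""
    out = []
    for tp in range(n_pos + 1):
        fn = n_pos - tp
        for fp in range(n_neg + 1):
            tn = n_neg - fp
            if ppv_pct is not None:
                if tp + fp == 0:
                    continue
                if round(100.0 * tp / (tp + fp), decimals) != ppv_pct:
                    continue
            if npv_pct is not None:
                if tn + fn == 0:
                    continue
                if round(100.0 * tn / (tn + fn), decimals) != npv_pct:
                    continue
            if f1 is not None:
                if 2 * tp + fp + fn == 0:
                    continue
                if round(2.0 * tp / (2 * tp + fp + fn), decimals) != f1:
                    continue
            out.append((tp, fp, fn, tn))
    return out
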