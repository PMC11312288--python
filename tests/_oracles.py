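"""Independent brute-force oracles used to cross-check the implementation.

Each function here is deliberately naive (loops, direct definitions) and
shares no code with the package paths it checks.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini–Hochberg step-up, one comparison at a time."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = running_min
    return q


def euclidean_loops(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(x.shape[1]):
                s += (x[i, k] - x[j, k]) ** 2
            d[i, j] = s**0.5
    return d


def abs_cosine_loops(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dot = float(np.dot(x[i], x[j]))
            c[i, j] = abs(dot) / (np.linalg.norm(x[i]) * np.linalg.norm(x[j]))
    return c


def collapse_loops(table: pd.DataFrame) -> dict[tuple, float]:
    """Mean Ct per (gene, group, animal) computed by explicit accumulation."""
    sums: dict[tuple, list[float]] = {}
    for _, row in table.iterrows():
        sums.setdefault((row["gene"], row["group"], row["animal"]), []).append(row["ct"])
    return {k: sum(v) / len(v) for k, v in sums.items()}


def running_sum_walk(scores: np.ndarray, hit: np.ndarray, w: float) -> np.ndarray:
    """Step-by-step enrichment walk from the definition."""
    n = len(scores)
    n_hit = int(hit.sum())
    weights = np.abs(scores) ** w
    total = weights[hit].sum()
    out = []
    cur = 0.0
    for i in range(n):
        if hit[i]:
            cur += (weights[i] / total) if total > 0 else 1.0 / n_hit
        else:
            cur -= 1.0 / (n - n_hit)
        out.append(cur)
    return np.array(out)
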