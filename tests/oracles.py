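"""Independent brute-force oracles for matrix-based texture families.

Everything here is a deliberately naive double-loop implementation, written
from the family definitions and kept independent of the package's
vectorized code paths.
"""

from __future__ import annotations

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def naive_cooccurrence(levels, valid, offset, Ng):
    """Symmetric normalized GLCM by explicit pixel-pair enumeration."""
    dr, dc = offset
    P = np.zeros((Ng, Ng))
    h, w = levels.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and valid[r, c] and valid[r2, c2]:
                P[levels[r, c], levels[r2, c2]] += 1
                P[levels[r2, c2], levels[r, c]] += 1
    total = P.sum()
    return P / total if total else P


def naive_runs(levels, valid, offset):
    """All maximal same-level runs along one direction by pixel walking."""
    dr, dc = offset
    h, w = levels.shape
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            prev_same = (
                0 <= pr < h and 0 <= pc < w and valid[pr, pc] and valid[r, c]
                and levels[pr, pc] == levels[r, c]
            )
            if valid[r, c] and not prev_same:
                starts.append((r, c))
    runs = []
    for r, c in starts:
        length, level = 0, levels[r, c]
        while 0 <= r < h and 0 <= c < w and valid[r, c] and levels[r, c] == level:
            length += 1
            r, c = r + dr, c + dc
        runs.append((int(level), length))
    return runs


def naive_abs_diff_hist(levels, valid, offset, Ng):
    """Histogram of |level difference| at one displacement."""
    dr, dc = offset
    h, w = levels.shape
    counts = np.zeros(Ng)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and valid[r, c] and valid[r2, c2]:
                counts[abs(int(levels[r, c]) - int(levels[r2, c2]))] += 1
    return counts


def naive_ngtdm(levels, valid, window, Ng):
    """Amadasun s(i) / n(i) arrays by explicit neighbourhood loops."""
    h, w = levels.shape
    half = window // 2
    s = np.zeros(Ng)
    n = np.zeros(Ng)
    for r in range(half, h - half):
        for c in range(half, w - half):
            if not valid[r, c]:
                continue
            neigh = []
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    if (dr, dc) == (0, 0):
                        continue
                    if valid[r + dr, c + dc]:
                        neigh.append(float(levels[r + dr, c + dc]))
            if not neigh:
                continue
            g = int(levels[r, c])
            s[g] += abs(g - float(np.mean(neigh)))
            n[g] += 1
    return s, n


def naive_delta_stats(levels, valid, offset):
    """(mean |diff|, mean diff^2, n) over valid pairs at one displacement."""
    dr, dc = offset
    h, w = levels.shape
    diffs = []
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and valid[r, c] and valid[r2, c2]:
                diffs.append(abs(int(levels[r, c]) - int(levels[r2, c2])))
    if not diffs:
        return np.nan, np.nan, 0
    d = np.asarray(diffs, dtype=float)
    return float(d.mean()), float((d ** 2).mean()), len(d)


def naive_auc(scores, labels):
    """AUC by exhaustive positive/negative pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_inscribed_square(mask):
    """(side, top_row, left_col) by exhaustive search, ties smallest row/col."""
    h, w = mask.shape
    for side in range(min(h, w), 0, -1):
        for r in range(h - side + 1):
            for c in range(w - side + 1):
                if mask[r : r + side, c : c + side].all():
                    return side, r, c
    return 0, 0, 0
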