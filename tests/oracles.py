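"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_auroc(y, s):
    """O(n^2) pairwise ranking probability, ties half credit."""
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_aupr(y, s):
    """Exhaustive threshold enumeration of the step-wise PR curve."""
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    n_pos = y.sum()
    pts = []
    for i in range(len(s)):
        if i + 1 < len(s) and s[i + 1] == s[i]:
            continue
        tp = y[:i + 1].sum()
        pts.append((tp / n_pos, tp / (i + 1)))
    area, prev_r = 0.0, 0.0
    for r, p in pts:
        area += (r - prev_r) * p
        prev_r = r
    return area
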