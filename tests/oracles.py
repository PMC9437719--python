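"""Independent brute-force reference implementations used as test oracles.

Deliberately naive (plain loops, Counter-based majorities) so they share no
code path with the package implementations they check.
"""

from collections import Counter
from itertools import permutations

import numpy as np


def brute_force_five_steps(positions, codes, window_bp, per_side=2):
    """Naive re-statement of the five bin-construction rules.

    Returns a list of dicts (start, end, snp_count, vector) per bin.
    """
    positions = list(positions)
    codes = [list(row) for row in codes]
    n = len(codes[0]) if codes else 0

    # step i: fixed tiles, per-progeny majority, tie/all-missing -> -1
    windows = {}
    for pos, row in zip(positions, codes):
        windows.setdefault((pos - 1) // window_bp, []).append((pos, row))
    keys = sorted(windows)
    mat, w_first, w_last, w_count = [], [], [], []
    for k in keys:
        members = windows[k]
        call = []
        for j in range(n):
            cnt = Counter(r[j] for _, r in members if r[j] >= 0)
            if not cnt:
                call.append(-1)
                continue
            top = cnt.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                call.append(-1)
            else:
                call.append(top[0][0])
        mat.append(call)
        w_first.append(min(p for p, _ in members))
        w_last.append(max(p for p, _ in members))
        w_count.append(len(members))

    # step ii: fill missing with strict majority of <=per_side nearest
    # non-missing calls on each side (simultaneous)
    filled = [row[:] for row in mat]
    for j in range(n):
        for i, row in enumerate(mat):
            if row[j] >= 0:
                continue
            above = [mat[k][j] for k in range(i - 1, -1, -1) if mat[k][j] >= 0][:per_side]
            below = [mat[k][j] for k in range(i + 1, len(mat)) if mat[k][j] >= 0][:per_side]
            picks = above + below
            if not picks:
                continue
            cnt = Counter(picks)
            code, count = cnt.most_common(1)[0]
            if 2 * count > len(picks):
                filled[i][j] = code
    mat = filled

    # step iii: fill missing runs whose flanks are identical
    for j in range(n):
        i = 0
        while i < len(mat):
            if mat[i][j] >= 0:
                i += 1
                continue
            k = i
            while k < len(mat) and mat[k][j] < 0:
                k += 1
            if i > 0 and k < len(mat) and mat[i - 1][j] == mat[k][j]:
                for t in range(i, k):
                    mat[t][j] = mat[i - 1][j]
            i = k

    # step iv: singleton correction against immediate neighbours (simultaneous)
    corrected = [row[:] for row in mat]
    for i in range(1, len(mat) - 1):
        for j in range(n):
            a, b, c = mat[i - 1][j], mat[i][j], mat[i + 1][j]
            if a >= 0 and c >= 0 and a == c and b >= 0 and b != a:
                corrected[i][j] = a
    mat = corrected

    # step v: merge runs of identical vectors (missing matches missing)
    bins = []
    i = 0
    while i < len(mat):
        k = i
        while k + 1 < len(mat) and mat[k + 1] == mat[i]:
            k += 1
        bins.append(
            {
                "start": w_first[i],
                "end": w_last[k],
                "snp_count": sum(w_count[i:k + 1]),
                "vector": list(mat[i]),
            }
        )
        i = k + 1
    return bins


def brute_force_best_order(d, w, objective):
    """Exhaustive search over all marker permutations for the ordering
    objective; returns the minimal objective value."""
    m = d.shape[0]
    best = np.inf
    for perm in permutations(range(m)):
        best = min(best, objective(list(perm), d, w))
    return best
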