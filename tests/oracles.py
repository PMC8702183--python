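"""Independent brute-force references used by the oracle-equivalence tests.

Deliberately shares no code with the package: plain-Python DP alignment
with its own traceback, and a literal transcription of the greedy
clustering rule without prefilters or fast paths.
"""

import numpy as np


def nw_identity(a, b):
    """Identity from a +1/-1/-2 global alignment, gaps as mismatches."""
    n, m = len(a), len(b)
    score = np.full((n + 1, m + 1), -np.inf)
    score[0, :] = -2.0 * np.arange(m + 1)
    score[:, 0] = -2.0 * np.arange(n + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        prev = score[i - 1]
        cur = score[i]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (1.0 if ai == b[j - 1] else -1.0)
            cur[j] = max(diag, prev[j] - 2.0, cur[j - 1] - 2.0)
    i, j, matches, cols = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            1.0 if a[i - 1] == b[j - 1] else -1.0
        ):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] - 2.0:
            i -= 1
        else:
            j -= 1
        cols += 1
    return matches / cols


def brute_force_greedy(uniques, threshold=0.97):
    """Reference greedy clusterer: (centroid, total size) pairs."""
    ordered = sorted(uniques, key=lambda u: (-u.size, u.sequence))
    centroids, sizes = [], []
    for rec in ordered:
        for ci, c in enumerate(centroids):
            if nw_identity(rec.sequence, c) >= threshold:
                sizes[ci] += rec.size
                break
        else:
            centroids.append(rec.sequence)
            sizes.append(rec.size)
    return list(zip(centroids, sizes))
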