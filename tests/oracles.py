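"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: plain-Python IUPAC
expansion, a quadratic-time Gotoh local aligner with traceback, and
closed-form least squares.
"""

from __future__ import annotations

import math

# Written out independently of the package's table.
EXPANSIONS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -5, -2


def gotoh_local(query: str, subject: str):
    """Quadratic-time affine-gap local alignment.

    Gap of length L costs GAP_OPEN + (L-1)*GAP_EXTEND.  Returns
    (score, identity_pct, coverage_pct) where identity is matches over
    alignment columns and coverage is the aligned query span over query
    length.
    """
    n, m = len(query), len(subject)
    NEG = -(10**9)
    M = [[0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (consumes query)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consumes subject)
    best = (0, 0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if query[i - 1] == subject[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0) + s
            Ix[i][j] = max(M[i - 1][j] + GAP_OPEN, Ix[i - 1][j] + GAP_EXTEND)
            Iy[i][j] = max(M[i][j - 1] + GAP_OPEN, Iy[i][j - 1] + GAP_EXTEND)
            if M[i][j] > best[0]:
                best = (M[i][j], i, j)
    score, i, j = best
    if score <= 0:
        return 0, 0.0, 0.0
    # traceback from the best match cell
    matches = columns = 0
    qend = i
    state = "M"
    cur = score
    while cur > 0 and i > 0 and j > 0:
        if state == "M":
            columns += 1
            if query[i - 1] == subject[j - 1]:
                matches += 1
            s = MATCH if query[i - 1] == subject[j - 1] else MISMATCH
            prev = cur - s
            i, j = i - 1, j - 1
            if prev == 0:
                break
            for cand in ("M", "Ix", "Iy"):
                val = {"M": M, "Ix": Ix, "Iy": Iy}[cand][i][j]
                if val == prev:
                    state = cand
                    cur = prev
                    break
        elif state == "Ix":
            columns += 1
            if M[i - 1][j] + GAP_OPEN == cur:
                state, cur = "M", M[i - 1][j]
            else:
                cur = Ix[i - 1][j]
            i -= 1
        else:  # Iy
            columns += 1
            if M[i][j - 1] + GAP_OPEN == cur:
                state, cur = "M", M[i][j - 1]
            else:
                cur = Iy[i][j - 1]
            j -= 1
    qstart = i  # 0-based start of the aligned query region
    identity = 100.0 * matches / columns
    coverage = 100.0 * (qend - qstart) / len(query)
    return score, identity, coverage


def ols(xs, ys):
    """Closed-form simple least squares: (slope, intercept, r_squared)."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    syy = sum((y - my) ** 2 for y in ys)
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else 1.0
    return slope, intercept, r2


def log10(x):
    return math.log10(x)
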