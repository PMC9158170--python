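"""Independent brute-force oracles used only by the test suite."""

import numpy as np


def longest_common_substring(a: str, b: str) -> int:
    """O(n·m) dynamic-programming longest-common-substring length."""
    best = 0
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for ch in a.encode():
        cur = np.zeros(len(b) + 1, dtype=np.int64)
        match = bb == ch
        cur[1:][match] = prev[:-1][match] + 1
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best


def kruskal_wallis_bruteforce(groups):
    """Explicit rank-table Kruskal–Wallis H with tie correction, no shortcuts."""
    pooled = sorted(
        (v, gi) for gi, g in enumerate(groups) for v in g
    )
    n = len(pooled)
    # midranks by explicit tie-run averaging
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for t in range(i, j):
            ranks[t] = mid
        i = j
    rank_sums = [0.0] * len(groups)
    for (v, gi), r in zip(pooled, ranks):
        rank_sums[gi] += r
    h = 12.0 / (n * (n + 1)) * sum(
        rs**2 / len(g) for rs, g in zip(rank_sums, groups)
    ) - 3 * (n + 1)
    tie = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        t = j - i
        tie += t**3 - t
        i = j
    denom = 1.0 - tie / (n**3 - n)
    return h / denom if denom > 0 else 0.0


def dunn_z_bruteforce(groups, i, j):
    """Dunn z for one pair from the pooled explicit rank table."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    ranks = {}
    idx = 0
    while idx < n:
        jdx = idx
        while jdx < n and pooled[jdx][0] == pooled[idx][0]:
            jdx += 1
        mid = (idx + 1 + jdx) / 2.0
        for t in range(idx, jdx):
            ranks[t] = mid
        idx = jdx
    sums = [0.0] * len(groups)
    for t, (v, gi) in enumerate(pooled):
        sums[gi] += ranks[t]
    means = [s / len(g) for s, g in zip(sums, groups)]
    tie = 0.0
    idx = 0
    while idx < n:
        jdx = idx
        while jdx < n and pooled[jdx][0] == pooled[idx][0]:
            jdx += 1
        t = jdx - idx
        tie += t**3 - t
        idx = jdx
    var = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    se = (var * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))) ** 0.5
    return (means[i] - means[j]) / se
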