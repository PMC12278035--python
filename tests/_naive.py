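"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops over residues, pairs and counts,
deliberately sharing no code with the package's vectorised implementations.
"""

import math

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def naive_aac(seq):
    return [sum(1 for c in seq if c == aa) / len(seq) for aa in ALPHABET]


def naive_composition(seq, groups):
    return [sum(1 for c in seq if c in g) / len(seq) for g in groups]


def naive_distribution(seq, groups):
    out = []
    for g in groups:
        positions = [i + 1 for i, c in enumerate(seq) if c in g]
        if not positions:
            out += [0.0] * 5
            continue
        n = len(positions)
        picks = [positions[0],
                 positions[math.ceil(0.25 * n) - 1],
                 positions[math.ceil(0.50 * n) - 1],
                 positions[math.ceil(0.75 * n) - 1],
                 positions[-1]]
        out += [p / len(seq) for p in picks]
    return out


def naive_bivalent(seq, groups):
    def gid(c):
        return next(k for k, g in enumerate(groups) if c in g)
    counts = {frozenset(p): 0 for p in [(0, 1), (0, 2), (1, 2)]}
    for a, b in zip(seq, seq[1:]):
        key = frozenset((gid(a), gid(b)))
        if len(key) == 2 and key in counts:
            counts[key] += 1
    L = len(seq)
    return [counts[frozenset(p)] / (L - 1) for p in [(0, 1), (0, 2), (1, 2)]]


def naive_cc(seq, table1, table2, lg):
    v1 = [table1[c] for c in seq]
    v2 = [table2[c] for c in seq]
    m1 = sum(v1) / len(v1)
    m2 = sum(v2) / len(v2)
    total = 0.0
    for i in range(len(seq) - lg):
        total += (v1[i] - m1) * (v2[i + lg] - m2)
    return total / (len(seq) - lg)


def naive_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def naive_roc_auc(labels, scores):
    """Concordant-pair counting with half credit for ties."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
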