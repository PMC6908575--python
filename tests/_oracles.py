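"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written in plain Python over plain data structures and
deliberately shares no code with the package internals.
"""

import math
from math import comb


def align_score(read, ref, strand="top", match=1, mismatch=-1,
                gap_open=2, gap_extend=1, free_ref_ends=True):
    """Full-matrix three-state affine DP over strings; returns the best score."""
    n, m = len(read), len(ref)
    NEG = -math.inf

    def s(a, b):
        if a == b and a in "ACGT":
            return match
        if strand == "top" and b == "C" and a == "T":
            return match
        if strand == "bottom" and b == "G" and a == "A":
            return match
        return mismatch

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = 0.0 if free_ref_ends else -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        Y[i][0] = -(gap_open + (i - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = s(read[i - 1], ref[j - 1]) + max(
                M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_extend,
                          Y[i][j - 1] - gap_open)
            Y[i][j] = max(M[i - 1][j] - gap_open, Y[i - 1][j] - gap_extend,
                          X[i - 1][j] - gap_open)
    if free_ref_ends:
        return max(max(M[n][j], Y[n][j]) for j in range(m + 1))
    return max(M[n][m], X[n][m], Y[n][m])


def hyper_domains(fractions, min_meth, max_gap, min_cpgs):
    """All maximal valid runs as (i, j) index pairs, by exhaustive enumeration."""
    n = len(fractions)
    hyper = [f >= min_meth for f in fractions]
    valid = []
    for i in range(n):
        for j in range(i, n):
            if not (hyper[i] and hyper[j]):
                continue
            streak, ok = 0, True
            for k in range(i, j + 1):
                if hyper[k]:
                    streak = 0
                else:
                    streak += 1
                    if streak > max_gap:
                        ok = False
                        break
            if ok:
                valid.append((i, j))
    maximal = [
        (i, j) for (i, j) in valid
        if not any(a <= i and j <= b and (a, b) != (i, j) for (a, b) in valid)
    ]
    return sorted((i, j) for (i, j) in maximal if j - i + 1 >= min_cpgs)


def tss_class(tss, strand, repeats, edge_window):
    """Scan every repeat and re-derive the Up/UpEdge/none classification.

    ``repeats`` are (chrom, start, end) triples on the transcript's
    chromosome or not; returns only the class, not the winning repeat.
    """
    klass = "none"
    for chrom, start, end in repeats:
        if start <= tss < end:
            return "Up"
    for chrom, start, end in repeats:
        if strand == "+":
            d = tss - (end - 1)
        else:
            d = start - tss
        if 1 <= d <= edge_window:
            klass = "UpEdge"
    return klass


def fisher_two_sided(table):
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def parental_origin(offspring, mother, father):
    """Re-derivation of the trio rule: 'error', an origin map, or None."""
    mo, fa = set(mother), set(father)
    for allele in offspring:
        if allele not in mo and allele not in fa:
            return "error"
    x, y = offspring
    if x == y:
        return None
    options = []
    if x in mo and y in fa:
        options.append({x: "maternal", y: "paternal"})
    if y in mo and x in fa:
        options.append({y: "maternal", x: "paternal"})
    return options[0] if len(options) == 1 else None


# A fixed 5-leaf rooted tree used for MRCA cross-checks, as nested clades.
FIVE_LEAF_NEWICK = "(((human,chimp),macaque),(mouse,rat));"
FIVE_LEAF_CLADES = [
    {"human"}, {"chimp"}, {"macaque"}, {"mouse"}, {"rat"},
    {"human", "chimp"},
    {"human", "chimp", "macaque"},
    {"mouse", "rat"},
    {"human", "chimp", "macaque", "mouse", "rat"},
]


def mrca_leafset(present):
    """Smallest clade of the fixed tree containing all present species."""
    containing = [c for c in FIVE_LEAF_CLADES if set(present) <= c]
    return min(containing, key=len)
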