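"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively and separately from the package code paths
it validates: exhaustive scans, double loops and O(n^3) agglomeration.
"""

import itertools
from collections import Counter

import numpy as np

from ssrmarkers.genotypes import MISSING


def brute_force_ssrs(seq, motif_length=3, min_repeats=10):
    """Test every (start, phase) pair for a maximal perfect repeat, then apply
    the same greedy leftmost-longest selection contract."""
    seq = seq.upper()
    m = motif_length
    candidates = []
    for start in range(len(seq) - m * min_repeats + 1):
        unit = seq[start : start + m]
        if "N" in unit:
            continue
        if any(len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d) for d in range(1, m)):
            continue
        n_rep = 0
        pos = start
        while seq[pos : pos + m] == unit:
            n_rep += 1
            pos += m
        if n_rep < min_repeats:
            continue
        if start - m >= 0 and seq[start - m : start] == unit:
            continue  # not maximal on the left
        candidates.append((start, n_rep))
    candidates.sort(key=lambda c: (c[0], -c[1]))
    chosen = []
    cursor = 0
    for start, n_rep in candidates:
        if start < cursor:
            continue
        chosen.append((start, start + m * n_rep, seq[start : start + m], n_rep))
        cursor = start + m * n_rep
    return chosen


def tally_frequencies(matrix, locus, ids):
    counts = Counter()
    n = 0
    for aid in ids:
        call = matrix.call(aid, locus)
        if call is MISSING:
            continue
        counts[call[0]] += 1
        counts[call[1]] += 1
        n += 1
    return {a: c / (2 * n) for a, c in sorted(counts.items())}, n


def pic_double_loop(freqs):
    p = list(freqs)
    s = 1.0 - sum(x * x for x in p)
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            s -= 2 * p[i] ** 2 * p[j] ** 2
    return s


def pid_enumeration(freqs):
    """Sum of squared HWE genotype probabilities over all unordered genotypes."""
    p = list(freqs)
    total = 0.0
    for i in range(len(p)):
        for j in range(i, len(p)):
            prob = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            total += prob**2
    return total


def pairwise_mismatch_counts(matrix, max_t, min_shared_loci):
    """All-pairs identity matching, written independently of the library."""
    ids = matrix.accession_ids
    counts = {t: 0 for t in range(max_t + 1)}
    for a, b in itertools.combinations(ids, 2):
        shared = mism = 0
        for locus in matrix.loci:
            ca, cb = matrix.call(a, locus), matrix.call(b, locus)
            if ca is MISSING or cb is MISSING:
                continue
            shared += 1
            pair_a, pair_b = list(ca), list(cb)
            hits = 0
            for x in pair_a:
                if x in pair_b:
                    pair_b.remove(x)
                    hits += 1
            mism += 2 - hits
        if shared < min_shared_loci:
            continue
        for t in range(max_t + 1):
            if mism <= t:
                counts[t] += 1
    return counts


def naive_upgma_cophenetic(dist):
    """O(n^3) average-linkage agglomeration tracking cophenetic distances."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in itertools.combinations(keys, 2):
            val = d[frozenset((a, b))]
            if best is None or val < best[0]:
                best = (val, a, b)
        val, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = val
        merged = clusters[a] + clusters[b]
        na, nb = len(clusters[a]), len(clusters[b])
        del clusters[b]
        clusters[a] = merged
        for c in clusters:
            if c == a:
                continue
            key_ab = frozenset((a, c))
            d[key_ab] = (na * d[key_ab] + nb * d[frozenset((b, c))]) / (na + nb)
    return coph


def dice_from_sets(row_i, row_j):
    """Set-based Dice distance: 1 - 2|A∩B| / (|A| + |B|)."""
    a = len(row_i & row_j)
    return 1.0 - 2.0 * a / (len(row_i) + len(row_j))
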