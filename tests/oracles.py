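"""Independent brute-force re-implementations used as test oracles.

Everything here is written as literal loops over definitions, deliberately
sharing no code with the package.
"""

from __future__ import annotations


def naive_reduce(samples, alpha=1, beta=0.0):
    """Bits from comparing successive alpha-strided samples."""
    picked = [samples[i] for i in range(0, len(samples), alpha)]
    bits = []
    for t in range(1, len(picked)):
        bits.append(1 if picked[t] > beta + picked[t - 1] else 0)
    return bits


def naive_words(bits, m):
    words = []
    for k in range(len(bits) - m + 1):
        value = 0
        for bit in bits[k:k + m]:
            value = value * 2 + bit
        words.append(value)
    return words


def naive_counts(words, m):
    counts = {j: 0 for j in range(2 ** m)}
    for w in words:
        counts[w] += 1
    return counts


def naive_ranks(counts, m):
    """1-based ranks by descending count, ties toward the smaller value."""
    order = sorted(range(2 ** m), key=lambda j: (-counts[j], j))
    ranks = {}
    for position, j in enumerate(order):
        ranks[j] = position + 1
    return ranks


def naive_segment_distance(freqs1, ranks1, freqs2, ranks2, m):
    num = 0.0
    den = 0.0
    for j in range(2 ** m):
        num += abs(ranks1[j] - ranks2[j]) * freqs1[j] * freqs2[j]
        den += freqs1[j] * freqs2[j]
    if den == 0.0:
        return 1.0
    return num / ((2 ** m - 1) * den)


def naive_group_distance(profiles_a, profiles_b):
    """Mean of segment distances over the full cartesian product.

    Each profile is a (freqs, ranks, m) triple.
    """
    total = 0.0
    for fa, ra, m in profiles_a:
        for fb, rb, _ in profiles_b:
            total += naive_segment_distance(fa, ra, fb, rb, m)
    return total / (len(profiles_a) * len(profiles_b))


def naive_success_rate(values, baseline="row"):
    """Errors and rate from a square group-distance matrix (list of lists)."""
    n = len(values)
    errors = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if baseline == "row":
                bad = values[i][j] <= values[i][i]
            elif baseline == "col":
                bad = values[i][j] <= values[j][j]
            else:
                bad = values[i][j] <= values[i][i] or values[i][j] <= values[j][j]
            if bad:
                errors += 1
    return errors, 1.0 - errors / (n * (n - 1))
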