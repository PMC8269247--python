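"""Brute-force enumeration oracle for the umbrella statistic null
distribution, independent of the dynamic-programming implementation."""

import itertools

import numpy as np


def brute_force_sf(sizes, w):
    """Survival function of the umbrella statistic over all distinct
    arrangements of ranks 1..n into groups of the given sizes."""
    n = sum(sizes)
    max_a = int(sum(w[i, j] * sizes[i] * sizes[j]
                    for i in range(len(sizes)) for j in range(len(sizes))))
    counts = np.zeros(max_a + 1)
    labels = []
    for g, s in enumerate(sizes):
        labels.extend([g] * s)
    seen = set()
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        # perm[r] = group of rank r (ranks in increasing order)
        a = 0
        for r1 in range(n):
            for r2 in range(r1 + 1, n):
                if w[perm[r1], perm[r2]]:
                    a += 1
        counts[a] += 1
    sf = counts[::-1].cumsum()[::-1] / counts.sum()
    return sf
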