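"""Independent brute-force oracles, written from the definitions.

Everything here is deliberately naive (explicit loops, no shared code with
the package) so tests compare two independent routes to each statistic.
"""

import math
from itertools import combinations

import numpy as np


def diversity_oracle(dosages):
    """Per-locus (Ho, Hs, Fis) by direct genotype counting, one population."""
    dosages = np.asarray(dosages)
    n = dosages.shape[0]
    out = []
    for l in range(dosages.shape[1]):
        col = dosages[:, l]
        n_het = int((col == 1).sum())
        ho = n_het / n
        # allele frequencies from genotype counts
        p = float(col.sum()) / (2 * n)
        q = 1.0 - p
        hs = (n / (n - 1)) * (1.0 - (p * p + q * q) - ho / (2 * n))
        hs = min(max(hs, 0.0), 1.0)
        fis = 1.0 - ho / hs if hs > 0 else float("nan")
        out.append((ho, hs, fis))
    return out


def modified_rogers_pair(row_i, row_j):
    """Straight-from-formula MR over both alleles of every locus."""
    l = len(row_i)
    total = 0.0
    for xi, xj in zip(row_i, row_j):
        for allele_freqs in ((xi / 2.0, xj / 2.0), (1 - xi / 2.0, 1 - xj / 2.0)):
            total += (allele_freqs[0] - allele_freqs[1]) ** 2
    return math.sqrt(total / (2 * l))


def czekanowski_pair(row_i, row_j):
    l = len(row_i)
    total = 0.0
    for xi, xj in zip(row_i, row_j):
        total += abs(xi / 2.0 - xj / 2.0) + abs((1 - xi / 2.0) - (1 - xj / 2.0))
    return total / (2 * l)


def brute_force_core(values, size, kind):
    """Exhaustive optimum over all subsets of the given size."""
    n = values.shape[0]
    best_val, best_sub = None, None
    for sub in combinations(range(n), size):
        idx = list(sub)
        if kind == "AN":
            val = values[:, idx].min(axis=1).mean()
            better = best_val is None or val < best_val
        else:
            block = values[np.ix_(idx, idx)].copy()
            np.fill_diagonal(block, np.inf)
            val = block.min(axis=1).mean()
            better = best_val is None or val > best_val
        if better:
            best_val, best_sub = val, sub
    return best_val, best_sub


def hudson_fst(dosages, labels):
    """Hudson's Fst estimator (ratio of averages) for two populations."""
    nums, dens = [], []
    for l in range(dosages.shape[1]):
        d1 = dosages[labels == 0, l]
        d2 = dosages[labels == 1, l]
        n1, n2 = 2 * len(d1), 2 * len(d2)
        p1, p2 = d1.sum() / n1, d2.sum() / n2
        nums.append(
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        dens.append(p1 * (1 - p2) + p2 * (1 - p1))
    return float(np.sum(nums) / np.sum(dens))
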