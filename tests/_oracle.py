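"""Independent brute-force oracles for the summation-partition statistics.

Deliberately written as plain double loops over explicit carrier index sets —
no shared code with the vectorized implementation they are used to check.
"""

from __future__ import annotations

import numpy as np


def oracle_I1(y, carrier_sets, weights=None) -> float:
    """Direct summation of n_i^2 (mean_carrier_y - overall_mean)^2.

    ``weights`` overrides n_i (e.g. allele counts); carrier means are always
    over the carrier set.
    """
    y = list(map(float, y))
    ybar = sum(y) / len(y)
    total = 0.0
    for i, s in enumerate(carrier_sets):
        s = list(s)
        if not s:
            continue
        mean_i = sum(y[k] for k in s) / len(s)
        n_i = float(weights[i]) if weights is not None else float(len(s))
        total += n_i**2 * (mean_i - ybar) ** 2
    return total


def oracle_IA(y, carrier_sets, labels, n_clusters, dosages=None, mode="carrier") -> float:
    """Direct double summation over clusters and variants."""
    y = list(map(float, y))
    ybar = sum(y) / len(y)
    labels = list(labels)
    total = 0.0
    for j in range(1, n_clusters + 1):
        for i, s in enumerate(carrier_sets):
            sub = [k for k in s if labels[k] == j]
            if not sub:
                continue
            mean_ij = sum(y[k] for k in sub) / len(sub)
            if mode == "allele":
                n_ij = float(sum(dosages[k, i] for k in sub))
            else:
                n_ij = float(len(sub))
            total += n_ij**2 * (mean_ij - ybar) ** 2
    return total


def random_instance(rng: np.random.Generator, n_max=50, k_max=10, j_max=3):
    """A random small region: phenotype, rare dosages, ancestry labels."""
    n = int(rng.integers(3, n_max + 1))
    K = int(rng.integers(1, k_max + 1))
    J = int(rng.integers(1, j_max + 1))
    y = rng.normal(size=n)
    dosages = rng.choice([0, 1, 2], size=(n, K), p=[0.8, 0.15, 0.05]).astype(np.int8)
    labels = rng.integers(1, J + 1, size=n)
    return y, dosages, labels, J
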