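"""Independent brute-force oracles used to cross-check the implementation.

Everything here works from first principles on tiny inputs: joint
distributions are materialized as explicit tuple->count dicts, AUC is an
exhaustive count of concordant positive-negative pairs.  Nothing imports
the code paths under test.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations


def brute_entropy(*columns, base: float = 2.0) -> float:
    """Entropy of the empirical joint distribution of the given columns."""
    n = len(columns[0])
    counts = Counter(zip(*columns))
    return -sum((c / n) * math.log(c / n, base) for c in counts.values())


def brute_conditional_entropy(target_cols, given_cols, base: float = 2.0) -> float:
    """H(target | given) from the explicit joint distribution."""
    return brute_entropy(*target_cols, *given_cols, base=base) - brute_entropy(
        *given_cols, base=base
    )


def brute_channel_redundancy(columns, i: int, base: float = 2.0) -> float:
    """(H(X_i) - H(X_i | rest)) / H(X_i) via explicit distributions."""
    h_i = brute_entropy(columns[i], base=base)
    rest = [c for k, c in enumerate(columns) if k != i]
    h_cond = brute_conditional_entropy([columns[i]], rest, base=base)
    return (h_i - h_cond) / h_i


def brute_set_redundancy(columns, base: float = 2.0) -> float:
    """(H(joint) - sum_i H(X_i|rest)) / H(joint) via explicit distributions."""
    if len(columns) == 1:
        return 0.0
    h_joint = brute_entropy(*columns, base=base)
    cond_sum = 0.0
    for i in range(len(columns)):
        rest = [c for k, c in enumerate(columns) if k != i]
        cond_sum += brute_conditional_entropy([columns[i]], rest, base=base)
    return (h_joint - cond_sum) / h_joint


def brute_nmi(col_a, col_b, base: float = 2.0) -> float:
    """I(A;B)/H(A,B) from explicit distributions."""
    h_a = brute_entropy(col_a, base=base)
    h_b = brute_entropy(col_b, base=base)
    h_ab = brute_entropy(col_a, col_b, base=base)
    return (h_a + h_b - h_ab) / h_ab


def brute_auc(labels, scores) -> float:
    """Fraction of correctly ordered positive-negative pairs (ties = 1/2)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def brute_min_subset(columns, names, k: int, base: float = 2.0):
    """Minimum set redundancy over all C(n,k) subsets; lexicographic ties."""
    best = None
    for idx in combinations(range(len(columns)), k):
        r = brute_set_redundancy([columns[i] for i in idx], base=base)
        if best is None or r < best[1]:
            best = (tuple(names[i] for i in idx), r)
    return best
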