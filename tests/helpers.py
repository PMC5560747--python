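"""Independent oracles used across the test suite.

These deliberately avoid the library code paths they check: the alignment
oracle is a plain Gotoh dynamic program, the string-kernel oracle enumerates
substring pairs, and the AUC oracle counts concordant/discordant pairs.
"""

import math

import numpy as np


def sw_score_oracle(s1, s2, substitution, gap_open, gap_extend):
    """Quadratic-space affine-gap Smith-Waterman.

    A gap of length k costs gap_open + (k - 1) * gap_extend.
    """
    n, m = len(s1), len(s2)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in s1 (consume s2)
    F = np.full((n + 1, m + 1), NEG)  # gap in s2 (consume s1)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + substitution.score(s1[i - 1], s2[j - 1])
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def gs_kernel_oracle(s, t, L, sigma_p, sigma_c, table):
    """Naive triple loop over substring lengths and start offsets."""
    total = 0.0
    for l in range(1, L + 1):
        for i in range(len(s) - l + 1):
            for j in range(len(t) - l + 1):
                a = table.encode(s[i : i + l]).ravel()
                b = table.encode(t[j : j + l]).ravel()
                total += math.exp(-((i - j) ** 2) / (2 * sigma_p**2)) * math.exp(
                    -float(((a - b) ** 2).sum()) / (2 * sigma_c**2)
                )
    return total


def auc_pair_count_oracle(labels, scores):
    """AUC as the probability a random positive outranks a random negative,
    ties counted half."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels]
    neg = scores[~labels]
    total = len(pos) * len(neg)
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / total


def pearson_oracle(x, y):
    """Textbook sum formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = math.sqrt(n * (x**2).sum() - x.sum() ** 2) * math.sqrt(
        n * (y**2).sum() - y.sum() ** 2
    )
    return num / den
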