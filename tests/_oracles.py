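"""Independent brute-force oracles for texture statistics.

Deliberately naive double-loop implementations, kept free of any shared code
with the package so they can serve as an independent cross-check.
"""

from __future__ import annotations

import math

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_brute(levels, n_levels, distance, angle):
    """Ordered-pair GLCM by explicit pixel enumeration; 0 marks invalid."""
    dr, dc = OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = len(levels), len(levels[0])
    counts = [[0.0] * n_levels for _ in range(n_levels)]
    total = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            a, b = levels[r][c], levels[r2][c2]
            if a > 0 and b > 0:
                counts[a - 1][b - 1] += 1.0
                total += 1
    if total == 0:
        raise ValueError("no valid pairs")
    return [[v / total for v in row] for row in counts]


def texture_params_brute(P):
    """Contrast, correlation, energy, homogeneity by scalar double loops."""
    n = len(P)
    contrast = energy = homogeneity = cross = 0.0
    pi = [sum(P[i]) for i in range(n)]
    pj = [sum(P[i][j] for i in range(n)) for j in range(n)]
    for i in range(n):
        for j in range(n):
            p = P[i][j]
            contrast += (i - j) ** 2 * p
            energy += p * p
            homogeneity += p / (1 + (i - j) ** 2)
            cross += (i + 1) * (j + 1) * p
    mu_i = sum((i + 1) * pi[i] for i in range(n))
    mu_j = sum((j + 1) * pj[j] for j in range(n))
    var_i = sum((i + 1 - mu_i) ** 2 * pi[i] for i in range(n))
    var_j = sum((j + 1 - mu_j) ** 2 * pj[j] for j in range(n))
    sd = math.sqrt(var_i * var_j)
    correlation = 0.0 if sd < 1e-12 else (cross - mu_i * mu_j) / sd
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
    }
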