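"""Grantham (1974) amino-acid substitution distances.

The distance between two residues combines three physicochemical
properties -- atomic composition c, polarity p and molecular volume v --

    D(i, j) = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and rho = 50.723 chosen
so that the mean over all 190 residue pairs is 100.  Rounding D to the
nearest integer reproduces the published matrix (e.g. Ile-Leu 5, Arg-Lys 26,
Trp-Cys 215).
"""

from __future__ import annotations

import math

# composition, polarity, volume per residue (Grantham 1974, Table 1)
PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.00, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.00, 8.1, 31.0),
    "V": (0.00, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.00, 5.2, 111.0),
    "F": (0.00, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.00, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399
RHO = 50.723


def grantham_distance(aa1: str, aa2: str) -> float:
    """Exact (unrounded) Grantham distance between two one-letter residues.

    Raises KeyError for a nonstandard residue; identity pairs return 0.
    """
    c1, p1, v1 = PROPERTIES[aa1]
    c2, p2, v2 = PROPERTIES[aa2]
    return RHO * math.sqrt(
        ALPHA * (c1 - c2) ** 2 + BETA * (p1 - p2) ** 2 + GAMMA * (v1 - v2) ** 2
    )


def grantham_matrix_value(aa1: str, aa2: str) -> int:
    """Grantham distance rounded to the nearest integer (published matrix)."""
    return round(grantham_distance(aa1, aa2))
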