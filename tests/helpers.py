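"""Independent oracles used by the test suite.

Everything here is deliberately written without reusing the package's own
computation paths: residue nitrogen counts come from a separately typed
table, isotope patterns from direct enumeration of heavy-isotope placements,
and scan scoring from a plain re-implementation of the scoring formula.
"""

from __future__ import annotations

import math
from itertools import product

# nitrogen atoms per residue, typed independently of the package tables
RESIDUE_N = {
    "G": 1, "A": 1, "S": 1, "P": 1, "V": 1, "T": 1, "C": 1, "L": 1, "I": 1,
    "N": 2, "D": 1, "Q": 2, "K": 2, "E": 1, "M": 1, "H": 3, "F": 1, "R": 4,
    "Y": 1, "W": 2,
}

# residue CHNOS formulas (amino acid minus water), independent copy
RESIDUE_FORMULA = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}

# standard isotope tables: per element, list of (nominal shift, mass, abundance)
ISOTOPES = {
    "C": [(0, 12.0, 0.9893), (1, 13.00335483780, 0.0107)],
    "H": [(0, 1.00782503207, 0.999885), (1, 2.01410177785, 0.000115)],
    "N": [(0, 14.0030740048, 0.99636), (1, 15.0001088989, 0.00364)],
    "O": [(0, 15.9949146196, 0.99757), (1, 16.99913170, 0.00038), (2, 17.99916100, 0.00205)],
    "S": [(0, 31.97207100, 0.9499), (1, 32.97145876, 0.0075), (2, 33.96786690, 0.0425),
          (4, 35.96708076, 0.0001)],
}


def nitrogen_count(sequence: str) -> int:
    return sum(RESIDUE_N[ch] for ch in sequence)


def formula_of(sequence: str) -> tuple[int, int, int, int, int]:
    c = h = n = o = s = 0
    for ch in sequence:
        rc, rh, rn, ro, rs = RESIDUE_FORMULA[ch]
        c, h, n, o, s = c + rc, h + rh, n + rn, o + ro, s + rs
    return c, h + 2, n, o + 1, s  # + H2O


def _element_states(element: str, n_atoms: int, p15: float | None, prune: float):
    """Enumerate (nominal shift, mass sum, probability) for n atoms of one element."""
    table = ISOTOPES[element]
    if element == "N" and p15 is not None:
        table = [(0, 14.0030740048, 1.0 - p15), (1, 15.0001088989, p15)]
    k = len(table)
    states: list[tuple[int, float, float]] = []
    # counts over the non-principal isotopes; the principal takes the rest
    heavy = table[1:]
    max_each = [n_atoms] * len(heavy)
    for counts in product(*(range(0, m + 1) for m in max_each)):
        if sum(counts) > n_atoms:
            continue
        n0 = n_atoms - sum(counts)
        prob = math.factorial(n_atoms)
        prob /= math.factorial(n0)
        for c in counts:
            prob /= math.factorial(c)
        prob *= table[0][2] ** n0
        for c, (_, _, ab) in zip(counts, heavy):
            prob *= ab**c
        if prob < prune:
            continue
        shift = sum(c * s for c, (s, _, _) in zip(counts, heavy))
        mass = n0 * table[0][1] + sum(c * m for c, (_, m, _) in zip(counts, heavy))
        states.append((shift, mass, prob))
    return states


def brute_force_distribution(sequence: str, p15: float, floor: float = 1e-5,
                             prune: float = 1e-14):
    """Isotopologue pattern by explicit enumeration over heavy-atom placements.

    Returns (masses, abundances) per nominal peak, floor-truncated relative
    to the base peak and renormalized — an independent oracle for small
    peptides.
    """
    c, h, n, o, s = formula_of(sequence)
    per_element = [
        _element_states("C", c, None, prune),
        _element_states("H", h, None, prune),
        _element_states("N", n, p15, prune),
        _element_states("O", o, None, prune),
    ]
    if s:
        per_element.append(_element_states("S", s, None, prune))
    bins: dict[int, tuple[float, float]] = {}
    for combo in product(*per_element):
        prob = 1.0
        shift = 0
        mass = 0.0
        for sh, m, p in combo:
            prob *= p
            shift += sh
            mass += m
        if prob < prune:
            continue
        ab, wm = bins.get(shift, (0.0, 0.0))
        bins[shift] = (ab + prob, wm + prob * mass)
    shifts = sorted(bins)
    abundances = [bins[k][0] for k in shifts]
    masses = [bins[k][1] / bins[k][0] for k in shifts]
    peak = max(abundances)
    kept = [(m, a) for m, a in zip(masses, abundances) if a >= floor * peak]
    total = sum(a for _, a in kept)
    return [m for m, _ in kept], [a / total for _, a in kept]


def rescore_envelope(peaks, n_prev, tol_iso_ppm=20.0, w_c=1.0, w_p=1.0, penalty=0.0):
    """Plain re-implementation of the total scan score for oracle comparisons.

    ``peaks`` is a list of (intensity, abs_ppm) pairs; the first entry is the
    gating peak.
    """
    total_int = sum(i for i, _ in peaks)
    w_ppm = sum((i / total_int) * p for i, p in peaks)
    coverage = len(peaks) / n_prev
    return math.log10(peaks[0][0]) + w_c * coverage - w_p * (w_ppm / tol_iso_ppm) - penalty
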