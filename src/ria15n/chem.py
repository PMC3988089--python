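"""Peptide elemental composition, isotope masses and ¹⁵N envelope templates.

The theoretical envelope of a peptide under ¹⁵N metabolic labeling is modelled
as a ladder of n_N + 1 peaks: the ¹⁴N monoisotopic peak followed by one peak
per possible ¹⁵N substitution, spaced by Δm(¹⁵N−¹⁴N)/z.  ¹³C fine structure is
deliberately not part of the template (it is absorbed by the ppm matching
tolerance downstream); full isotopologue distributions are provided separately
for the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np

# IUPAC/CODATA monoisotopic masses (Da)
MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}
MASS_PROTON = 1.00727646688
MASS_15N = 15.0001088989
#: mass difference of a single ¹⁴N → ¹⁵N exchange (≈ 0.9970349 Da)
DELTA_15N = MASS_15N - MASS["N"]
MASS_WATER = 2 * MASS["H"] + MASS["O"]

#: natural abundance of ¹⁵N
NATURAL_15N = 0.00364

# per-element isotope tables: (nominal mass shift, monoisotopic mass, abundance)
_ISOTOPES = {
    "C": [(0, 12.0, 0.9893), (1, 13.00335483780, 0.0107)],
    "H": [(0, 1.00782503207, 0.999885), (1, 2.01410177785, 0.000115)],
    "N": [(0, 14.0030740048, 1.0 - NATURAL_15N), (1, MASS_15N, NATURAL_15N)],
    "O": [
        (0, 15.9949146196, 0.99757),
        (1, 16.99913170, 0.00038),
        (2, 17.99916100, 0.00205),
    ],
    "S": [
        (0, 31.97207100, 0.9499),
        (1, 32.97145876, 0.0075),
        (2, 33.96786690, 0.0425),
        (4, 35.96708076, 0.0001),
    ],
}

# residue formulas (amino acid minus water): (C, H, N, O, S)
RESIDUES: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}


@dataclass(frozen=True)
class ElementalComposition:
    """CHNOS atom counts of a neutral peptide (residues + one water)."""

    c: int
    h: int
    n: int
    o: int
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name.upper()} count")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.c + other.c,
            self.h + other.h,
            self.n + other.n,
            self.o + other.o,
            self.s + other.s,
        )

    @property
    def monoisotopic_mass(self) -> float:
        return (
            self.c * MASS["C"]
            + self.h * MASS["H"]
            + self.n * MASS["N"]
            + self.o * MASS["O"]
            + self.s * MASS["S"]
        )

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.c, self.h, self.n, self.o, self.s)


def composition_from_sequence(
    sequence: str,
    fixed_modifications: Mapping[str, ElementalComposition] | None = None,
) -> ElementalComposition:
    """Elemental composition of a peptide from its one-letter sequence.

    ``fixed_modifications`` maps a residue letter to a composition delta added
    once per occurrence (e.g. carbamidomethyl on C); none are applied by
    default.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    c = h = n = o = s = 0
    for ch in sequence:
        try:
            rc, rh, rn, ro, rs = RESIDUES[ch]
        except KeyError:
            raise ValueError(f"unknown amino-acid residue {ch!r} in {sequence!r}") from None
        c += rc
        h += rh
        n += rn
        o += ro
        s += rs
    comp = ElementalComposition(c, h + 2, n, o + 1, s)  # + one water
    if fixed_modifications:
        for ch in sequence:
            delta = fixed_modifications.get(ch)
            if delta is not None:
                comp = comp + delta
    return comp


@dataclass(frozen=True)
class Template:
    """The searched ¹⁵N envelope of one peptide at one charge state.

    ``full_mz`` holds all n_N + 1 theoretical m/z positions; ``slots`` indexes
    the currently active subset (initially all of them, shrinking under
    propagation from later time points).  m/z values never change once
    computed.
    """

    sequence: str
    charge: int
    full_mz: np.ndarray
    slots: np.ndarray

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        object.__setattr__(self, "full_mz", np.asarray(self.full_mz, dtype=float))
        object.__setattr__(self, "slots", np.asarray(self.slots, dtype=int))
        if np.any(np.diff(self.full_mz) <= 0):
            raise ValueError("template m/z values must be strictly increasing")
        if self.slots.size and (
            self.slots.min() < 0
            or self.slots.max() >= self.full_mz.size
            or np.any(np.diff(self.slots) <= 0)
        ):
            raise ValueError("slots must be strictly increasing indices into full_mz")

    @property
    def mz(self) -> np.ndarray:
        """Active theoretical m/z positions."""
        return self.full_mz[self.slots]

    @property
    def size(self) -> int:
        return int(self.slots.size)

    @property
    def full_size(self) -> int:
        """Theoretical envelope size, n_N + 1."""
        return int(self.full_mz.size)

    def subset(self, slots) -> "Template":
        return Template(self.sequence, self.charge, self.full_mz, np.asarray(slots, dtype=int))

    def reset(self) -> "Template":
        return Template(self.sequence, self.charge, self.full_mz, np.arange(self.full_mz.size))


def build_template(
    sequence: str,
    charge: int,
    fixed_modifications: Mapping[str, ElementalComposition] | None = None,
) -> Template:
    """Theoretical n_N + 1 ¹⁵N-substitution ladder for a peptide/charge.

    Entry 0 is the ¹⁴N monoisotopic m/z, (M + z·m_proton)/z; entry i sits
    i·Δm(¹⁵N)/z above it.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    comp = composition_from_sequence(sequence, fixed_modifications)
    mono_mz = (comp.monoisotopic_mass + charge * MASS_PROTON) / charge
    k = np.arange(comp.n + 1)
    full_mz = mono_mz + k * (DELTA_15N / charge)
    return Template(sequence, charge, full_mz, k.copy())


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Aggregated isotopologue pattern of a peptide at ¹⁵N enrichment ``p15``.

    One entry per nominal isotope peak: centroid neutral mass
    (abundance-weighted within the peak) and relative abundance summing to 1.
    """

    masses: np.ndarray
    abundances: np.ndarray
    p15: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(self, "abundances", np.asarray(self.abundances, dtype=float))
        if self.masses.size != self.abundances.size:
            raise ValueError("masses and abundances must have equal length")
        if np.any(np.diff(self.masses) <= 0):
            raise ValueError("masses must be strictly increasing")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be >= 0")
        if abs(float(self.abundances.sum()) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


def _element_pattern(element: str, p15: float | None = None):
    """(abundance, abundance-weighted mass) arrays indexed by nominal shift."""
    table = _ISOTOPES[element]
    if element == "N" and p15 is not None:
        table = [(0, MASS["N"], 1.0 - p15), (1, MASS_15N, p15)]
    size = max(shift for shift, _, _ in table) + 1
    a = np.zeros(size)
    m = np.zeros(size)
    for shift, mass, ab in table:
        a[shift] += ab
        m[shift] += ab * mass
    return a, m


def _convolve(a1, m1, a2, m2):
    # abundances multiply; first moments add: E[m] convolves as cross terms
    return np.convolve(a1, a2), np.convolve(m1, a2) + np.convolve(a1, m2)


def _pattern_power(a, m, n: int):
    """Pattern of n independent atoms of one element (repeated squaring)."""
    ra, rm = np.array([1.0]), np.array([0.0])
    base_a, base_m = a, m
    while n:
        if n & 1:
            ra, rm = _convolve(ra, rm, base_a, base_m)
        n >>= 1
        if n:
            base_a, base_m = _convolve(base_a, base_m, base_a, base_m)
    return ra, rm


@lru_cache(maxsize=512)
def _distribution_cached(comp_tuple, p15: float, floor: float):
    c, h, n, o, s = comp_tuple
    a, m = np.array([1.0]), np.array([0.0])
    for element, count in (("C", c), ("H", h), ("N", n), ("O", o), ("S", s)):
        if count == 0:
            continue
        ea, em = _element_pattern(element, p15 if element == "N" else None)
        pa, pm = _pattern_power(ea, em, count)
        a, m = _convolve(a, m, pa, pm)
    keep = a >= floor * a.max()
    a_kept = a[keep]
    # m carries abundance-weighted absolute mass sums, so this is the
    # centroid neutral mass of each nominal peak
    centroid = m[keep] / a_kept
    a_kept = a_kept / a_kept.sum()
    return centroid, a_kept


def isotopologue_distribution(
    comp: ElementalComposition, p15: float, floor: float = 1e-5
) -> IsotopologueDistribution:
    """Aggregated isotope pattern of ``comp`` with ¹⁵N abundance set to ``p15``.

    Convolves the natural-abundance patterns of C, H, O and S with a
    binomial(n_N, p15) pattern for nitrogen; isotopologues are aggregated per
    nominal mass shift, peaks below ``floor`` × the base peak are dropped and
    the rest renormalized to sum to 1.
    """
    if not 0.0 <= p15 <= 1.0:
        raise ValueError("p15 must lie in [0, 1]")
    masses, abundances = _distribution_cached(comp.as_tuple(), float(p15), float(floor))
    return IsotopologueDistribution(masses.copy(), abundances.copy(), p15)
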