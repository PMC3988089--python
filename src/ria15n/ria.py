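"""Relative Isotope Abundance (RIA) and downstream filtering/aggregation.

RIA = A15 / (A14 + A15): the labeled fraction of a peptide's envelope
intensity.  Because no ¹⁵N has been incorporated at the first time point,
every peak present in the noise-filtered TP0 spectrum is attributed to the
¹⁴N (natural-abundance) species; at later time points the TP0 relative
intensities split each overlapping peak into its natural and enriched parts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .extraction import PickedSpectrum
from .spectra_io import PeptideTarget


@dataclass(frozen=True)
class ReferenceEnvelope:
    """The TP0 (natural-abundance) envelope used to split later spectra."""

    slots: tuple[int, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.slots:
            raise ValueError("reference envelope must contain at least one slot")
        if any(i <= 0 for i in self.intensities):
            raise ValueError("reference intensities must be > 0")

    @property
    def relative(self) -> np.ndarray:
        """Intensities relative to the first reference slot (entry 0 = 1)."""
        arr = np.asarray(self.intensities)
        return arr / arr[0]


def reference_envelope(tp0_picked: PickedSpectrum) -> ReferenceEnvelope:
    """Build the ¹⁴N reference from the noise-filtered TP0 spectrum."""
    if not tp0_picked.peaks:
        raise ValueError("empty TP0 spectrum: no reference envelope; RIA undefined")
    return ReferenceEnvelope(
        tuple(p.slot for p in tp0_picked.peaks),
        tuple(p.intensity for p in tp0_picked.peaks),
    )


def split_a14_a15(picked: PickedSpectrum, reference: ReferenceEnvelope) -> tuple[float, float]:
    """Split one spectrum's intensity into natural (A14) and labeled (A15).

    The expected natural intensity at reference slot i is the TP0 envelope
    rescaled to this spectrum's intensity at the reference's first slot
    (0 if that slot is absent).  Each reference slot contributes
    min(observed, expected) to A14; everything else — the excess above the
    expectation and all non-reference slots — is A15.  A15 is computed as
    total − A14 so the split conserves the total picked intensity exactly.
    """
    if not picked.peaks:
        return 0.0, 0.0
    by_slot = {p.slot: p.intensity for p in picked.peaks}
    anchor = by_slot.get(reference.slots[0], 0.0)
    scale = anchor / reference.intensities[0]
    expected = {
        slot: ref_int * scale for slot, ref_int in zip(reference.slots, reference.intensities)
    }
    # accumulate both sums in the same order so that a spectrum identical to
    # the reference yields a15 == 0.0 exactly
    a14 = 0.0
    total = 0.0
    for p in picked.peaks:
        total += p.intensity
        if p.slot in expected:
            a14 += min(p.intensity, expected[p.slot])
    a15 = max(0.0, total - a14)  # guard against last-ulp rounding
    return a14, a15


def compute_ria(a14: float, a15: float) -> float | None:
    """RIA = A15/(A14+A15); None when the spectrum carries no intensity."""
    if a14 < 0 or a15 < 0:
        raise ValueError("A14 and A15 must be >= 0")
    total = a14 + a15
    if total == 0:
        return None
    return a15 / total


@dataclass
class RIASeries:
    """Per-time-point RIA trajectory of one peptide with its filter verdict."""

    peptide: PeptideTarget
    time_points: tuple[float, ...]
    ria: list[float | None]
    a14: list[float | None]
    a15: list[float | None]
    passed: bool = False
    failure_reason: str | None = None

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.ria)


def postprocess_filter(ria_values, epsilon: float = 0.0) -> tuple[bool, str | None]:
    """Monotonicity verdict for one RIA trajectory.

    ¹⁵N incorporation can only raise the labeled fraction, so a trustworthy
    trajectory never decreases.  A peptide passes iff no time point is
    missing and RIA never drops by more than ``epsilon`` between consecutive
    time points; the first offending time point is reported.
    """
    for k, v in enumerate(ria_values):
        if v is None:
            return False, f"missing time point at index {k}"
    for k in range(1, len(ria_values)):
        if ria_values[k] < ria_values[k - 1] - epsilon:
            return False, f"RIA decrease at index {k}"
    return True, None


def build_ria_series(
    target: PeptideTarget,
    time_points,
    picked_series,
    epsilon: float = 0.0,
) -> RIASeries:
    """RIA trajectory for one peptide from its chronological picked spectra.

    ``picked_series`` holds the (noise-filtered at TP0) PickedSpectrum or
    None per time point.  Without a usable TP0 envelope no RIA can be
    computed at all.
    """
    n = len(time_points)
    ria: list[float | None] = [None] * n
    a14: list[float | None] = [None] * n
    a15: list[float | None] = [None] * n
    tp0 = picked_series[0]
    if tp0 is not None and tp0.peaks:
        reference = reference_envelope(tp0)
        for k, ps in enumerate(picked_series):
            if ps is None or not ps.peaks:
                continue
            a14[k], a15[k] = split_a14_a15(ps, reference)
            ria[k] = compute_ria(a14[k], a15[k])
    passed, reason = postprocess_filter(ria, epsilon)
    return RIASeries(target, tuple(time_points), ria, a14, a15, passed, reason)


@dataclass
class ProteinReport:
    """Per-protein mean RIA trajectory with its linear-regression diagnostic."""

    accession: str
    time_points: tuple[float, ...]
    mean_ria: list[float | None]
    slope: float | None
    intercept: float | None
    r_squared: float
    n_peptides: int  # peptides passing the post-processing filter
    n_peptides_total: int


def protein_aggregate(series_list: list[RIASeries], time_points) -> ProteinReport:
    """Aggregate one protein's passing peptides and regress mean RIA on time.

    Ordinary least squares of the per-time-point mean RIA against the time
    labels; a protein whose peptides were all filtered out is reported with
    R² = 0 by convention.
    """
    if not series_list:
        raise ValueError("no peptide series supplied")
    accession = series_list[0].peptide.accession
    passing = [s for s in series_list if s.passed]
    n = len(time_points)
    if not passing:
        return ProteinReport(
            accession, tuple(time_points), [None] * n, None, None, 0.0, 0, len(series_list)
        )
    matrix = np.array([[s.ria[k] for k in range(n)] for s in passing], dtype=float)
    mean_ria = matrix.mean(axis=0)
    fit = stats.linregress(np.asarray(time_points, dtype=float), mean_ria)
    r2 = float(fit.rvalue**2)
    if math.isnan(r2):  # zero-variance trajectory: diagnostic undefined, use 0
        r2 = 0.0
    return ProteinReport(
        accession,
        tuple(time_points),
        [float(v) for v in mean_ria],
        float(fit.slope),
        float(fit.intercept),
        r2,
        len(passing),
        len(series_list),
    )


def absolute_coverage(picked: PickedSpectrum | None, n_max: int) -> float:
    """Slot coverage against the constant theoretical envelope size n_N + 1."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if picked is None:
        return 0.0
    return picked.n_picked / n_max
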