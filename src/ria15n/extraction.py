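"""Template-driven envelope extraction from MS1 time series.

The extractor walks the labeling series in reverse chronological order, from
the maximally labeled run (largest envelope, best isotope-peak signal) down
to the unlabeled one.  In each run it picks peaks scan-by-scan against the
current template, filters co-eluting interferences, scores every scan and
keeps the best one; the slots recovered there become the template for the
next (earlier) run, so the searched envelope can only shrink — noise peaks
that appear out of nowhere at early time points are never picked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import Template, build_template
from .config import RunConfig
from .spectra_io import PeptideTarget, Scan, select_window


@dataclass(frozen=True)
class PickedPeak:
    """One raw peak matched to a template slot."""

    slot: int
    mz: float
    intensity: float
    ppm: float  # signed deviation from the theoretical m/z


@dataclass(frozen=True)
class ScoreComponents:
    """Per-scan quality score of a picked envelope.

    total = i_mip0 + w_c * coverage - w_p * (w_ppm / tol_iso_ppm) - penalty
    """

    i_mip0: float
    w_ppm: float
    coverage: float
    penalty: float
    total: float


@dataclass
class PickedSpectrum:
    """Peaks of one peptide picked from one scan, with score components."""

    peptide: PeptideTarget | None
    time_point: float | None
    scan_rt: float | None
    peaks: list[PickedPeak] = field(default_factory=list)
    score: ScoreComponents | None = None

    def __post_init__(self) -> None:
        slots = [p.slot for p in self.peaks]
        if any(b <= a for a, b in zip(slots, slots[1:])):
            raise ValueError("picked slots must be strictly increasing")

    def __bool__(self) -> bool:
        return bool(self.peaks)

    @property
    def n_picked(self) -> int:
        return len(self.peaks)

    @property
    def slots(self) -> list[int]:
        return [p.slot for p in self.peaks]

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def total_intensity(self) -> float:
        return float(self.intensities.sum()) if self.peaks else 0.0


def _most_abundant_in_window(mz: np.ndarray, inten: np.ndarray, target: float, tol_ppm: float):
    """Index of the most abundant raw peak within ±tol_ppm of target, or None."""
    delta = target * tol_ppm * 1e-6
    lo = int(np.searchsorted(mz, target - delta, side="left"))
    hi = int(np.searchsorted(mz, target + delta, side="right"))
    if hi <= lo:
        return None
    return lo + int(np.argmax(inten[lo:hi]))


def _ppm(observed: float, theoretical: float) -> float:
    return 1e6 * (observed - theoretical) / theoretical


def pick_peaks(
    scan: Scan, template: Template, tol_mono_ppm: float, tol_iso_ppm: float
) -> PickedSpectrum:
    """Match one scan against the template, most-abundant-in-window per slot.

    The first template entry is the gate: if no raw peak lies within
    ±tol_mono_ppm of it, nothing at all is picked.  Each later entry is
    searched within ±tol_iso_ppm; entries without a match are simply absent.
    """
    if template.size == 0:
        raise ValueError("template must be non-empty")
    if tol_mono_ppm <= 0 or tol_iso_ppm <= 0:
        raise ValueError("tolerances must be > 0")
    mz, inten = scan.mz, scan.intensity
    targets = template.mz
    slots = template.slots
    first = _most_abundant_in_window(mz, inten, targets[0], tol_mono_ppm)
    if first is None:
        return PickedSpectrum(None, None, scan.rt)
    peaks = [
        PickedPeak(int(slots[0]), float(mz[first]), float(inten[first]), _ppm(mz[first], targets[0]))
    ]
    for k in range(1, targets.size):
        j = _most_abundant_in_window(mz, inten, targets[k], tol_iso_ppm)
        if j is not None:
            peaks.append(
                PickedPeak(int(slots[k]), float(mz[j]), float(inten[j]), _ppm(mz[j], targets[k]))
            )
    return PickedSpectrum(None, None, scan.rt, peaks)


def coelution_filter(
    scan: Scan,
    template: Template,
    picked: PickedSpectrum,
    ratio_threshold: float = 3.0,
    tol_iso_ppm: float = 20.0,
) -> PickedSpectrum:
    """Remove/re-pick peaks attributed to co-eluting analytes.

    Scanning the picked peaks in ascending slot order, a peak more than
    ``ratio_threshold`` times as intense as its predecessor is treated as a
    co-eluting interference when it is also prominent on its high-m/z side
    (more than the ratio above its successor, or the last picked peak): a
    partially labeled envelope is bimodal, and on the rising flank of the
    ¹⁵N-shifted component a large successor is the expected shape, not an
    interference.  The offending peak is deleted from a working copy of the
    raw data and its slot re-picked from the remaining peaks in the slot
    window; this repeats until no peak is removed.  The first picked peak
    has no predecessor and is never removed.  Terminates because every
    iteration deletes one raw data point.
    """
    if not picked.peaks:
        return picked
    mz = scan.mz.copy()
    inten = scan.intensity.copy()
    slot_mz = {int(s): float(m) for s, m in zip(template.slots, template.mz)}
    peaks = list(picked.peaks)
    while True:
        offender = None
        for k in range(1, len(peaks)):
            if peaks[k].intensity > ratio_threshold * peaks[k - 1].intensity and (
                k == len(peaks) - 1
                or peaks[k].intensity > ratio_threshold * peaks[k + 1].intensity
            ):
                offender = k
                break
        if offender is None:
            break
        bad = peaks[offender]
        j = int(np.searchsorted(mz, bad.mz, side="left"))
        if j >= mz.size or mz[j] != bad.mz:  # already gone; drop the slot
            peaks.pop(offender)
            continue
        mz = np.delete(mz, j)
        inten = np.delete(inten, j)
        target = slot_mz[bad.slot]
        j2 = _most_abundant_in_window(mz, inten, target, tol_iso_ppm)
        if j2 is None:
            peaks.pop(offender)
        else:
            peaks[offender] = PickedPeak(
                bad.slot, float(mz[j2]), float(inten[j2]), _ppm(mz[j2], target)
            )
    return PickedSpectrum(picked.peptide, picked.time_point, picked.scan_rt, peaks)


def penalty_check(
    scan: Scan,
    picked: PickedSpectrum,
    tol_ppm: float = 10.0,
    low: float = 0.5,
    high: float = 2.0,
    penalty_value: float = 3.0,
) -> float:
    """Penalty if the gating peak looks like an isotope peak of another peptide.

    The observed spacing Δm of the first two picked peaks is projected one
    step below the first peak; if the most abundant raw peak within ±tol_ppm
    of that position has intensity strictly between ``low``× and ``high``×
    the first peak's, the penalty applies.
    """
    if len(picked.peaks) < 2:
        return 0.0
    first, second = picked.peaks[0], picked.peaks[1]
    target = first.mz - (second.mz - first.mz)
    j = _most_abundant_in_window(scan.mz, scan.intensity, target, tol_ppm)
    if j is None:
        return 0.0
    candidate = float(scan.intensity[j])
    if low * first.intensity < candidate < high * first.intensity:
        return penalty_value
    return 0.0


def score_spectrum(
    picked: PickedSpectrum, scan: Scan, n_prev: int, config: RunConfig
) -> ScoreComponents | None:
    """Total score of one picked envelope; None if it cannot be scored.

    Components: log10 intensity of the gating peak, intensity-weighted mean
    absolute ppm deviation, slot coverage relative to the previous time
    point, and the interference penalty.
    """
    if not picked.peaks:
        return None
    if n_prev < 1:
        raise ValueError("n_prev must be >= 1")
    i0 = picked.peaks[0].intensity
    if i0 <= 0:
        return None
    intensities = picked.intensities
    weights = intensities / intensities.sum()
    w_ppm = float(np.sum(weights * np.abs([p.ppm for p in picked.peaks])))
    coverage = picked.n_picked / n_prev
    penalty = penalty_check(
        scan,
        picked,
        tol_ppm=config.penalty_tol_ppm,
        low=config.penalty_low,
        high=config.penalty_high,
        penalty_value=config.penalty_value,
    )
    i_mip0 = math.log10(i0)
    total = (
        i_mip0
        + config.w_coverage * coverage
        - config.w_ppm * (w_ppm / config.tol_iso_ppm)
        - penalty
    )
    return ScoreComponents(i_mip0, w_ppm, coverage, penalty, total)


def best_scan(
    scans: list[Scan], template: Template, n_prev: int, config: RunConfig
) -> PickedSpectrum | None:
    """Pick/filter/score every scan in the window; return the top scorer.

    A single scan is used, never an average of scans.  Ties go to the
    earliest retention time; None means no scan yielded a scoreable envelope.
    """
    best: PickedSpectrum | None = None
    for scan in scans:
        ps = pick_peaks(scan, template, config.tol_mono_ppm, config.tol_iso_ppm)
        if not ps:
            continue
        ps = coelution_filter(
            scan, template, ps, config.coelution_ratio, config.tol_iso_ppm
        )
        if not ps:
            continue
        score = score_spectrum(ps, scan, n_prev, config)
        if score is None:
            continue
        ps.score = score
        if best is None or score.total > best.score.total:
            best = ps
    return best


def propagate_template(template: Template, picked: PickedSpectrum | None) -> Template:
    """Template for the next (earlier) time point.

    Only the slots recovered at the just-processed time point are kept; their
    theoretical m/z values are untouched.  If nothing was picked, the full
    theoretical template is restored.
    """
    if picked is None or not picked.peaks:
        return template.reset()
    return template.subset(picked.slots)


def tp0_noise_filter(picked: PickedSpectrum, template: Template) -> PickedSpectrum:
    """Truncate the TP0 envelope at its first gap.

    At the unlabeled time point only the natural-abundance envelope should
    remain; walking the current template's slot sequence from the smallest
    picked slot upward, everything after the first missing slot is removed.
    """
    if not picked.peaks:
        return picked
    present = {p.slot: p for p in picked.peaks}
    slot_seq = [int(s) for s in template.slots]
    start = picked.peaks[0].slot
    kept: list[PickedPeak] = []
    for s in slot_seq[slot_seq.index(start):]:
        if s in present:
            kept.append(present[s])
        else:
            break
    return PickedSpectrum(picked.peptide, picked.time_point, picked.scan_rt, kept, picked.score)


def extract_time_series(
    target: PeptideTarget,
    runs: list[tuple[float, list[Scan]]],
    config: RunConfig,
) -> list[tuple[float, PickedSpectrum | None]]:
    """Extract one peptide's envelope at every time point.

    ``runs`` holds (time-point label, MS1 scans) chronologically.  Processing
    goes from TP_MAX down to TP0 with template propagation in between; at
    TP_MAX the full theoretical template is searched and the previous-count
    baseline is its size n_N + 1.  The TP0 result is additionally passed
    through the gap-truncation noise filter.  Results are returned in
    chronological order; a time point without a scoreable envelope yields
    None.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 time points")
    full = build_template(target.sequence, target.charge)
    template = full
    n_prev = full.full_size
    results: dict[int, PickedSpectrum | None] = {}
    for i in range(len(runs) - 1, -1, -1):
        tp, scans = runs[i]
        window = select_window(scans, target.rt_min, config.rt_window_min)
        ps = best_scan(window, template, n_prev, config)
        if ps is not None:
            if i == 0:
                ps = tp0_noise_filter(ps, template)
            ps.peptide = target
            ps.time_point = tp
        results[i] = ps if (ps is not None and ps.peaks) else None
        template = propagate_template(full, results[i])
        n_prev = results[i].n_picked if results[i] is not None else full.full_size
    return [(tp, results[i]) for i, (tp, _) in enumerate(runs)]
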