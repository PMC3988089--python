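"""Ground-truthed simulation of partial-¹⁵N LC/MS labeling series.

Each simulated peptide is a mixture of an "old pool" at natural isotopic
abundance and a "new pool" synthesized under ¹⁵N feeding at high enrichment;
the old-pool fraction shrinks over the time course, so the true labeled
fraction (RIA) grows.  Runs are rendered as centroided MS1 scan sets with
Gaussian chromatographic elution, m/z jitter, multiplicative intensity noise
and uniform baseline noise peaks, optionally with co-eluting interferent
peaks — the statistical structure the extractor assumes, with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import (
    MASS_PROTON,
    NATURAL_15N,
    RESIDUES,
    build_template,
    composition_from_sequence,
    isotopologue_distribution,
)
from .spectra_io import Scan, write_mzml

#: default study layout: five runs at 24 h labeling intervals
DEFAULT_TIME_POINTS = (0.0, 24.0, 48.0, 72.0, 96.0)
#: default ¹⁵N enrichment of newly synthesized protein
DEFAULT_ENRICHMENT = 0.95


@dataclass(frozen=True)
class GroundTruthPeptide:
    """One simulated peptide with its per-time-point species mixture.

    ``mixtures[k]`` lists (fraction, ¹⁵N enrichment) pairs for time point k;
    fractions sum to 1 and the old pool carries the natural ¹⁵N abundance.
    """

    sequence: str
    charge: int
    accession: str
    rt_center: float  # minutes
    rt_sigma: float  # minutes
    base_abundance: float
    mixtures: tuple[tuple[tuple[float, float], ...], ...]

    def __post_init__(self) -> None:
        for mixture in self.mixtures:
            fractions = [f for f, _ in mixture]
            if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
                raise ValueError("species fractions must be >= 0 and sum to 1")


@dataclass(frozen=True)
class Interferent:
    """A co-eluting foreign peak overlapping one slot of a target envelope."""

    target_index: int
    slot: int
    offset_ppm: float = 8.0
    intensity_factor: float = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition and noise model of the simulated LC/MS runs."""

    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    scan_interval_min: float = 0.2
    rt_pad_min: float = 6.0
    mz_jitter_ppm: float = 2.0
    intensity_sigma: float = 0.05  # log-normal sigma of multiplicative noise
    noise_peaks_per_scan: int = 50
    noise_intensity_mean: float = 1000.0
    mz_range: tuple[float, float] = (300.0, 1600.0)
    min_intensity: float = 10.0
    seed: int = 0


def random_tryptic_peptide(rng: np.random.Generator, min_len: int = 8, max_len: int = 18) -> str:
    """A random peptide ending in K/R, drawn uniformly over residues."""
    residues = sorted(RESIDUES)
    length = int(rng.integers(min_len, max_len + 1))
    body = "".join(rng.choice(residues) for _ in range(length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def linear_turnover_mixtures(
    time_points, rate_per_hour: float, enrichment: float = DEFAULT_ENRICHMENT
):
    """Mixtures whose true RIA grows linearly as rate × time (clipped at 1)."""
    mixtures = []
    for t in time_points:
        new = min(rate_per_hour * t, 1.0)
        mixtures.append(((1.0 - new, NATURAL_15N), (new, enrichment)))
    return tuple(mixtures)


def true_ria(gt: GroundTruthPeptide, tp_index: int) -> float:
    """Ground-truth labeled fraction: the mixture weight of the new pool(s)."""
    return float(
        sum(f for f, p in gt.mixtures[tp_index] if p > NATURAL_15N)
    )


def simulate_envelope(gt: GroundTruthPeptide, tp_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free composite stick spectrum of one peptide at one time point.

    Sum over mixture species of fraction × isotopologue pattern, placed at
    (mass + z·m_proton)/z and scaled to the peptide's base abundance; sticks
    closer than 1 mDa are merged.  Total intensity equals the base abundance.
    """
    comp = composition_from_sequence(gt.sequence)
    mz_parts: list[np.ndarray] = []
    int_parts: list[np.ndarray] = []
    for fraction, p15 in gt.mixtures[tp_index]:
        if fraction <= 0:
            continue
        dist = isotopologue_distribution(comp, p15)
        mz_parts.append((dist.masses + gt.charge * MASS_PROTON) / gt.charge)
        int_parts.append(dist.abundances * fraction * gt.base_abundance)
    mz = np.concatenate(mz_parts)
    inten = np.concatenate(int_parts)
    order = np.argsort(mz, kind="stable")
    return _merge_close(mz[order], inten[order], tol=1e-3)


def _merge_close(mz: np.ndarray, inten: np.ndarray, tol: float):
    """Merge sticks within ``tol`` m/z (intensity-weighted centroid)."""
    if mz.size == 0:
        return mz, inten
    out_mz: list[float] = []
    out_int: list[float] = []
    acc_mz = mz[0] * inten[0]
    acc_int = inten[0]
    last = mz[0]
    for m, i in zip(mz[1:], inten[1:]):
        if m - last < tol:
            acc_mz += m * i
            acc_int += i
        else:
            out_mz.append(acc_mz / acc_int)
            out_int.append(acc_int)
            acc_mz, acc_int = m * i, i
        last = m
    out_mz.append(acc_mz / acc_int)
    out_int.append(acc_int)
    return np.array(out_mz), np.array(out_int)


def _scenario_rates(rng: np.random.Generator, n_proteins: int) -> np.ndarray:
    # per-protein turnover 0.002–0.008 RIA/h: 0.19–0.77 after 96 h
    return rng.uniform(0.002, 0.008, size=n_proteins)


def make_scenario(
    n_peptides: int = 50,
    peptides_per_protein: int = 3,
    time_points=DEFAULT_TIME_POINTS,
    enrichment: float = DEFAULT_ENRICHMENT,
    seed: int = 0,
    interference: bool = False,
) -> tuple[list[GroundTruthPeptide], list[Interferent], SimulationConfig]:
    """Build the default simulated study.

    Peptides are grouped into proteins sharing one linear turnover rate;
    elution apexes spread over the gradient, abundances log-uniform.  With
    ``interference`` on, every peptide gets one co-eluting 4× interferent
    peak on a slot inside its labeled envelope region.
    """
    rng = np.random.default_rng(seed)
    n_proteins = max(1, -(-n_peptides // peptides_per_protein))
    rates = _scenario_rates(rng, n_proteins)
    peptides: list[GroundTruthPeptide] = []
    interferents: list[Interferent] = []
    seen: set[tuple[str, int]] = set()
    for i in range(n_peptides):
        protein = i // peptides_per_protein
        while True:
            seq = random_tryptic_peptide(rng)
            charge = int(rng.integers(2, 4))
            if (seq, charge) not in seen:
                seen.add((seq, charge))
                break
        gt = GroundTruthPeptide(
            sequence=seq,
            charge=charge,
            accession=f"PROT{protein:04d}",
            rt_center=float(rng.uniform(8.0, 42.0)),
            rt_sigma=0.25,
            base_abundance=float(10 ** rng.uniform(5.3, 6.3)),
            mixtures=linear_turnover_mixtures(time_points, rates[protein], enrichment),
        )
        peptides.append(gt)
        if interference:
            n_n = composition_from_sequence(seq).n
            slot = max(2, round(enrichment * n_n) - 1)
            interferents.append(Interferent(target_index=i, slot=slot))
    return peptides, interferents, SimulationConfig(time_points=tuple(time_points), seed=seed)


def simulate_runs(
    gt_peptides: list[GroundTruthPeptide],
    config: SimulationConfig,
    interferents: list[Interferent] | None = None,
) -> list[tuple[float, list[Scan]]]:
    """Render all runs of the experiment as in-memory MS1 scan lists.

    Deterministic under the config seed: same seed, same peak lists.
    """
    rng = np.random.default_rng(config.seed)
    interferents = interferents or []
    rt_lo = min(g.rt_center for g in gt_peptides) - config.rt_pad_min
    rt_hi = max(g.rt_center for g in gt_peptides) + config.rt_pad_min
    scan_times = np.arange(max(rt_lo, 0.0), rt_hi, config.scan_interval_min)
    envelopes = {
        (i, k): simulate_envelope(g, k)
        for i, g in enumerate(gt_peptides)
        for k in range(len(config.time_points))
    }
    interferent_mz = {}
    for itf in interferents:
        gt = gt_peptides[itf.target_index]
        template = build_template(gt.sequence, gt.charge)
        interferent_mz[itf.target_index] = (
            template.full_mz[itf.slot] * (1.0 + itf.offset_ppm * 1e-6),
            itf.intensity_factor * gt.base_abundance,
        )
    runs: list[tuple[float, list[Scan]]] = []
    for k, tp in enumerate(config.time_points):
        scans: list[Scan] = []
        for t in scan_times:
            mz_parts: list[np.ndarray] = []
            int_parts: list[np.ndarray] = []
            for i, gt in enumerate(gt_peptides):
                gauss = np.exp(-0.5 * ((t - gt.rt_center) / gt.rt_sigma) ** 2)
                if gauss < 1e-4:
                    continue
                emz, eint = envelopes[(i, k)]
                eint = eint * gauss
                jitter = rng.normal(0.0, config.mz_jitter_ppm * 1e-6, emz.size)
                noise = rng.lognormal(0.0, config.intensity_sigma, emz.size)
                mz_parts.append(emz * (1.0 + jitter))
                int_parts.append(eint * noise)
                if i in interferent_mz:
                    imz, iint = interferent_mz[i]
                    mz_parts.append(
                        np.array([imz * (1.0 + rng.normal(0.0, config.mz_jitter_ppm * 1e-6))])
                    )
                    int_parts.append(
                        np.array([iint * gauss * rng.lognormal(0.0, config.intensity_sigma)])
                    )
            if config.noise_peaks_per_scan:
                mz_parts.append(
                    rng.uniform(*config.mz_range, size=config.noise_peaks_per_scan)
                )
                int_parts.append(
                    rng.exponential(config.noise_intensity_mean, config.noise_peaks_per_scan)
                )
            if mz_parts:
                mz = np.concatenate(mz_parts)
                inten = np.concatenate(int_parts)
            else:
                mz = np.empty(0)
                inten = np.empty(0)
            keep = inten >= config.min_intensity
            mz, inten = mz[keep], inten[keep]
            order = np.argsort(mz, kind="stable")
            mz, inten = _merge_close(mz[order], inten[order], tol=1e-6)
            scans.append(Scan(float(t), mz, inten))
        runs.append((float(tp), scans))
    return runs


def write_ground_truth(gt_peptides, config, path) -> None:
    """Ground-truth RIA table: sequence, charge, time_point, true_ria."""
    lines = ["sequence\tcharge\ttime_point\ttrue_ria"]
    for gt in gt_peptides:
        for k, tp in enumerate(config.time_points):
            lines.append(f"{gt.sequence}\t{gt.charge}\t{tp:g}\t{true_ria(gt, k):.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_identifications_table(gt_peptides, path) -> None:
    lines = ["accession\tsequence\tcharge\trt_min"]
    for gt in gt_peptides:
        lines.append(f"{gt.accession}\t{gt.sequence}\t{gt.charge}\t{gt.rt_center:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_experiment(
    gt_peptides: list[GroundTruthPeptide],
    config: SimulationConfig,
    out_dir,
    interferents: list[Interferent] | None = None,
) -> dict[str, Path]:
    """Write the full simulated study: mzML per time point plus tables.

    Produces ``tp_<label>.mzML`` files, ``experiment.tsv``, ``ids.tsv`` and
    ``ground_truth.tsv`` in ``out_dir``, directly consumable by the pipeline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runs = simulate_runs(gt_peptides, config, interferents)
    mzml_paths: list[Path] = []
    for tp, scans in runs:
        path = out_dir / f"tp_{tp:g}.mzML"
        if path.exists():
            raise FileExistsError(f"output path already exists: {path}")
        write_mzml(scans, path)
        mzml_paths.append(path)
    exp_path = out_dir / "experiment.tsv"
    lines = ["time_point\tmzml_path"]
    for tp, path in zip(config.time_points, mzml_paths):
        lines.append(f"{tp:g}\t{path}")
    exp_path.write_text("\n".join(lines) + "\n")
    ids_path = out_dir / "ids.tsv"
    write_identifications_table(gt_peptides, ids_path)
    truth_path = out_dir / "ground_truth.tsv"
    write_ground_truth(gt_peptides, config, truth_path)
    return {
        "experiment": exp_path,
        "ids": ids_path,
        "ground_truth": truth_path,
        "mzml": mzml_paths,
    }
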