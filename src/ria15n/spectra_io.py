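"""mzML reading/writing, experiment and identification tables.

MS1 runs are parsed with a focused lxml-based mzML reader (binary arrays as
32/64-bit floats, optionally zlib-compressed; retention times normalized to
minutes); profile spectra are centroided on load.  The writer emits a minimal
standards-conformant mzML document (MS1 centroid spectra, 64-bit float
arrays, no compression) so that simulated runs go through the same reader as
real data.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .chem import RESIDUES

logger = logging.getLogger(__name__)


@dataclass
class Scan:
    """One centroided MS1 spectrum: retention time plus peak arrays."""

    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("m/z and intensity arrays must be 1-D and equally long")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z array must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class PeptideTarget:
    """One externally identified peptide to extract."""

    sequence: str
    charge: int
    rt_min: float
    accession: str
    peptide_id: str | None = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.rt_min < 0:
            raise ValueError("retention time must be >= 0")


@dataclass(frozen=True)
class Experiment:
    """Time-ordered labeling series: one mzML run per time point."""

    time_points: tuple[float, ...]
    paths: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.time_points) != len(self.paths):
            raise ValueError("time_points and paths must have equal length")
        if len(self.time_points) < 2:
            raise ValueError("an experiment needs at least 2 time points")
        if any(b <= a for a, b in zip(self.time_points, self.time_points[1:])):
            raise ValueError("time points must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_points)

    def reverse_chronological(self):
        """(time point, path) pairs from TP_MAX down to TP0."""
        return list(zip(self.time_points, self.paths))[::-1]


def read_experiment_file(path) -> Experiment:
    """Parse the two-column experiment TSV (``time_point<TAB>mzml_path``).

    Rows may appear in any order; the result is sorted chronologically.
    Duplicate time points are rejected.  Whether the mzML paths exist is
    checked at load time, not here.
    """
    path = Path(path)
    rows: list[tuple[float, str]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty experiment file")
    header = [c.strip() for c in lines[0].split("\t")]
    if header[:2] != ["time_point", "mzml_path"]:
        raise ValueError(f"{path}: header must start with 'time_point\\tmzml_path'")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        try:
            tp = float(fields[0])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: time_point {fields[0]!r} is not numeric") from None
        rows.append((tp, fields[1].strip()))
    tps = [tp for tp, _ in rows]
    if len(set(tps)) != len(tps):
        dup = sorted({t for t in tps if tps.count(t) > 1})
        raise ValueError(f"{path}: duplicate time point(s) {dup}")
    rows.sort(key=lambda r: r[0])
    return Experiment(tuple(r[0] for r in rows), tuple(r[1] for r in rows))


def read_identifications(path) -> list[PeptideTarget]:
    """Parse the identification TSV into peptide targets.

    Required columns: accession, sequence, charge, rt_min (any order,
    extra columns ignored).  Rows failing validation are skipped with a
    warning; a missing required column is a hard error.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty identification file")
    header = [c.strip() for c in lines[0].split("\t")]
    required = ["accession", "sequence", "charge", "rt_min"]
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    idx = {c: header.index(c) for c in required}
    targets: list[PeptideTarget] = []
    n_skipped = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            seq = fields[idx["sequence"]].strip().upper()
            if not seq or any(ch not in RESIDUES for ch in seq):
                raise ValueError(f"invalid sequence {seq!r}")
            charge = int(fields[idx["charge"]])
            rt = float(fields[idx["rt_min"]])
            targets.append(
                PeptideTarget(seq, charge, rt, fields[idx["accession"]].strip())
            )
        except (ValueError, IndexError) as exc:
            n_skipped += 1
            logger.warning("%s:%d: skipping row (%s)", path, lineno, exc)
    if n_skipped:
        logger.warning("%s: skipped %d invalid identification row(s)", path, n_skipped)
    return targets


def centroid_profile(scan: Scan) -> Scan:
    """Centroid a profile-mode spectrum.

    One centroid per local intensity maximum above zero; centroid m/z is the
    intensity-weighted mean over the maximum's contiguous raised region
    (split at local minima between adjacent maxima), centroid intensity is
    the region apex.
    """
    mz, inten = scan.mz, scan.intensity
    if mz.size == 0:
        return Scan(scan.rt, np.empty(0), np.empty(0), scan.ms_level)
    cmz: list[float] = []
    cint: list[float] = []
    nonzero = inten > 0
    i = 0
    n = mz.size
    while i < n:
        if not nonzero[i]:
            i += 1
            continue
        j = i
        while j < n and nonzero[j]:
            j += 1
        _centroid_run(mz[i:j], inten[i:j], cmz, cint)
        i = j
    return Scan(scan.rt, np.array(cmz), np.array(cint), scan.ms_level)


def _centroid_run(mz, inten, out_mz, out_int) -> None:
    """Centroid one contiguous nonzero run, splitting at local minima."""
    n = mz.size
    apexes = [
        k
        for k in range(n)
        if (k == 0 or inten[k] > inten[k - 1]) and (k == n - 1 or inten[k] >= inten[k + 1])
    ]
    if not apexes:
        apexes = [int(np.argmax(inten))]
    bounds = [0]
    for a, b in zip(apexes, apexes[1:]):
        bounds.append(a + int(np.argmin(inten[a : b + 1])))
    bounds.append(n)
    for k, apex in enumerate(apexes):
        lo, hi = bounds[k], bounds[k + 1]
        seg_i = inten[lo:hi]
        seg_m = mz[lo:hi]
        total = seg_i.sum()
        out_mz.append(float((seg_m * seg_i).sum() / total))
        out_int.append(float(inten[apex]))


# mzML cvParam accessions used by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_NS = "{http://psi.hupo.org/ms/mzml}"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda_elem) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array accession, values)."""
    dtype = np.float64
    compressed = False
    kind = None
    text = ""
    for child in bda_elem.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession")
            if acc == _ACC_F32:
                dtype = np.float32
            elif acc == _ACC_F64:
                dtype = np.float64
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc in (_ACC_MZ_ARRAY, _ACC_INT_ARRAY):
                kind = acc
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem) -> Scan | None:
    """One <spectrum> element -> centroided MS1 Scan, or None for non-MS1."""
    ms_level = 1
    profile = False
    rt = None
    mz = inten = None
    for child in elem.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession")
            if acc == _ACC_MS_LEVEL:
                ms_level = int(child.get("value"))
            elif acc == _ACC_PROFILE:
                profile = True
            elif acc == _ACC_SCAN_START:
                rt = float(child.get("value"))
                unit = (child.get("unitName") or "").lower()
                if "second" in unit:
                    rt /= 60.0
        elif name == "binaryDataArray":
            kind, values = _decode_binary_array(child)
            if kind == _ACC_MZ_ARRAY:
                mz = values
            elif kind == _ACC_INT_ARRAY:
                inten = values
    if ms_level != 1:
        return None
    if mz is None or inten is None or rt is None:
        raise ValueError("spectrum lacks m/z array, intensity array or scan start time")
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    # collapse duplicate m/z values so the ascending invariant holds
    if mz.size > 1 and np.any(np.diff(mz) <= 0):
        mz, inten = _merge_duplicates(mz, inten)
    scan = Scan(rt, mz, np.clip(inten, 0.0, None))
    if profile:
        scan = centroid_profile(scan)
    return scan


def load_run(mzml_path) -> list[Scan]:
    """All MS1 scans of one mzML run, centroided, in retention-time order."""
    mzml_path = Path(mzml_path)
    if not mzml_path.exists():
        raise FileNotFoundError(f"mzML file not found: {mzml_path}")
    scans: list[Scan] = []
    try:
        context = etree.iterparse(
            str(mzml_path), events=("end",), tag=(f"{_NS}spectrum", "spectrum")
        )
        for _, elem in context:
            scan = _parse_spectrum(elem)
            if scan is not None:
                scans.append(scan)
            elem.clear()
            while elem.getprevious() is not None:
                del elem.getparent()[0]
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"unreadable or truncated mzML file {mzml_path}: {exc}") from exc
    scans.sort(key=lambda s: s.rt)
    return scans


def _merge_duplicates(mz, inten):
    keep_mz: list[float] = []
    keep_int: list[float] = []
    for m, i in zip(mz, inten):
        if keep_mz and m <= keep_mz[-1]:
            keep_int[-1] += i
        else:
            keep_mz.append(m)
            keep_int.append(i)
    return np.array(keep_mz), np.array(keep_int)


def select_window(scans: list[Scan], rt_center: float, rt_window_full_width: float) -> list[Scan]:
    """Scans with |rt − center| ≤ window/2, chronological."""
    if rt_window_full_width <= 0:
        raise ValueError("retention-time window must be > 0")
    half = rt_window_full_width / 2.0
    rts = [s.rt for s in scans]
    lo = bisect_left(rts, rt_center - half)
    hi = bisect_right(rts, rt_center + half)
    return scans[lo:hi]


def load_scans(mzml_path, rt_center: float, rt_window_full_width: float) -> list[Scan]:
    """MS1 scans of one run restricted to a retention-time window."""
    return select_window(load_run(mzml_path), rt_center, rt_window_full_width)


def _b64(array: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{array.size}d", *array)).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="run0">
    <spectrumList count="{count}" defaultDataProcessingRef="dp0">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{length}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(scans: list[Scan], path) -> None:
    """Write MS1 centroid scans to a minimal mzML file.

    Scans must be in strictly increasing retention-time order; arrays are
    stored as uncompressed 64-bit floats so a read-back reproduces them
    within float round-trip.
    """
    rts = [s.rt for s in scans]
    if any(b <= a for a, b in zip(rts, rts[1:])):
        raise ValueError("scans must be in strictly increasing RT order")
    parts = [_MZML_HEADER.format(count=len(scans))]
    for i, scan in enumerate(scans):
        mz_b64 = _b64(scan.mz)
        int_b64 = _b64(scan.intensity)
        parts.append(
            _MZML_SPECTRUM.format(
                index=i,
                scan=i + 1,
                length=scan.n_peaks,
                rt=repr(float(scan.rt)),
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                int_len=len(int_b64),
                int_b64=int_b64,
            )
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))
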