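# Methods

## The measurement problem

In a partial ¹⁵N metabolic-labeling experiment an organism is fed a
¹⁵N-enriched nitrogen source; newly synthesized protein incorporates heavy
nitrogen while the pre-existing pool retains the natural isotope
composition.  The MS1 spectrum of a tryptic peptide then becomes a
*composite* of species at different enrichment levels: a natural-abundance
envelope at the light end and ¹⁵N-shifted envelopes spread over up to
n_N + 1 positions, where n_N is the peptide's nitrogen count.  Protein
turnover is quantified per peptide and time point as the Relative Isotope
Abundance,

    RIA = A15 / (A14 + A15),

the labeled fraction of the envelope's total intensity (A14: summed
intensity of natural-abundance peaks, A15: summed intensity of
¹⁵N-labeled peaks).  Under label feeding the RIA of a protein can only stay
constant or rise with time: degradation alone shrinks A14 (denominator) and
synthesis alone grows A15 (numerator).

## Extraction procedure

Inputs are (a) MS1 runs in mzML, one per labeling time point, centroid or
profile mode (profile data are centroided on load: local maxima,
intensity-weighted m/z over each raised region, apex intensity); (b) an
externally produced identification table (sequence, charge, reference
retention time, protein accession); (c) an experiment table mapping numeric
time-point labels to mzML paths.

1. **Template.**  For each peptide the theoretical envelope is the ladder of
   n_N + 1 m/z values: the ¹⁴N monoisotopic peak (M + z·m_H⁺)/z followed by
   one entry per possible ¹⁴N→¹⁵N exchange, spaced by Δm(¹⁵N)/z =
   0.9970349/z Da.  ¹³C fine structure is intentionally not modelled; at the
   matching tolerances used, ¹³C-containing isotopologues fall inside the
   ladder's windows for the first few peaks and are absorbed there.
2. **Reverse-chronological search.**  Runs are processed from the maximally
   labeled time point (largest envelope, best isotope-peak signal-to-noise)
   down to the unlabeled one.  After each time point the template is
   restricted to exactly the slots that were picked there (m/z values
   unchanged); if nothing was picked, the full theoretical template is
   restored.  The searched envelope therefore never grows backwards in
   time, which mirrors the biology (less label earlier) and prevents noise
   from entering the series at early time points.
3. **Per-scan picking.**  Within a retention-time window (default 10 min
   full width, ± 5 min around the reference RT) every MS1 scan is matched
   against the template: the most abundant raw peak within ± 10 ppm of the
   first template entry gates the spectrum — if it is absent nothing is
   picked; subsequent entries are matched within ± 20 ppm (wider because
   mass accuracy degrades with intensity), again most-abundant-in-window.
   Missing interior slots are simply absent at this stage.
4. **Co-elution filter.**  A picked peak more than 3× as intense as its
   predecessor *and* prominent on its high-m/z side (more than 3× its
   successor, or the last picked peak) is attributed to a co-eluting
   analyte: it is deleted from a working copy of the scan and its slot
   re-picked from the remaining raw peaks, iterating to a fixed point
   (each pass deletes one raw data point, so termination is guaranteed).
   The two-sided prominence condition is a deliberate design choice: a
   partially labeled composite envelope is bimodal, and on the rising flank
   of the ¹⁵N-shifted component an intensity jump past 3× is the expected
   shape.  A one-sided rule would iteratively remove the entire labeled
   flank of any well-separated two-pool envelope — the predecessor shrinks
   with every removal, so the cascade consumes the whole ¹⁵N region.  All
   boundary behaviour at the high-m/z end (where an interference cannot be
   distinguished from envelope by a successor) is one-sided, matching the
   removal of trailing interference spikes.
5. **Scan scoring.**  Each scan's picked envelope receives a total score

       TS = log10(I_gate) + w_c·C − w_p·(W_ppm / tol_iso) − P

   with C = N_picked/N_prev the coverage against the previous time point's
   pick count (the theoretical n_N + 1 at the maximally labeled time
   point), W_ppm the intensity-weighted mean absolute ppm deviation, and P
   a penalty of 3 applied when the gating peak looks like an isotope peak
   of another peptide: the observed spacing of the first two picked peaks
   is projected one step below the gate, and if the most abundant raw peak
   within ± 10 ppm of that position has intensity strictly between 0.5×
   and 2× the gate's, the penalty fires.  The additive combination with
   w_c = w_p = 1 is a design choice: each component's direction is fixed
   (intensity and coverage good, deviation and penalty bad) and the penalty
   magnitude 3 is commensurate with log10-intensity differences.  The
   highest-scoring single scan is kept — never an average across scans,
   which would blend in co-eluting isobaric envelopes.  Ties go to the
   earliest retention time for determinism.
6. **Noise truncation at TP0.**  The unlabeled spectrum defines the ¹⁴N
   envelope, so peaks there must be contiguous: walking the template's slot
   sequence from the first picked slot, everything after the first missing
   slot is discarded.

## RIA computation

All peaks of the noise-filtered TP0 spectrum are attributed to the ¹⁴N
species and define the reference envelope r_i = I_i(TP0)/I_first(TP0).  At
any later time point the expected natural contribution at reference slot i
is r_i scaled by that spectrum's intensity at the reference's first slot
(zero if absent).  Each reference slot contributes min(observed, expected)
to A14; the excess above the expectation and all non-reference slots are
A15.  A15 is computed as total − A14, so A14 + A15 equals the total picked
intensity exactly (to the last float bit) and RIA(TP0) = 0 identically.
Anchoring on the first reference slot (rather than rescaling by total ¹⁴N
abundance) is the simplest rule consistent with using the TP0 relative
intensities; it is isolated in one function (`ria.split_a14_a15`) so an
alternative split can be swapped in.

A peptide passes the post-processing filter iff every time point produced a
spectrum and the RIA never decreases between consecutive time points
(tolerance `postfilter_epsilon`, default 0 — strict).  Passing peptides are
averaged per protein and time point and the mean trajectory is fitted by
ordinary (unweighted) least squares against the time labels; slope,
intercept and R² are reported.  Proteins whose peptides were all filtered
out are reported with R² = 0 by convention.  A zero-variance mean
trajectory leaves the regression diagnostic undefined; it is also reported
as 0.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `rt_window_min` | 10 | min | full width, ± 5 min; tolerant of LC drift |
| `tol_mono_ppm` | 10 | ppm | gate-peak matching half-window |
| `tol_iso_ppm` | 20 | ppm | isotope peaks; accuracy drops with intensity |
| `coelution_ratio` | 3 | – | interference prominence threshold |
| `penalty_value` | 3 | score | commensurate with log10-intensity range |
| `penalty_low`, `penalty_high` | 0.5, 2.0 | – | open intensity band for the gate-interference check |
| `w_coverage`, `w_ppm` | 1, 1 | – | score weights |
| `postfilter_epsilon` | 0 | RIA | strict monotonicity |

## The simulator

`ria15n.synthetic` renders ground-truthed studies with the statistical
structure the extractor assumes.  Each peptide is a two-pool mixture: an
old pool at natural isotope abundance and a new pool at high ¹⁵N enrichment
(default 0.95), with the new-pool fraction growing linearly in time
(per-protein rates 0.002–0.008 h⁻¹ over the default 0/24/48/72/96 h
design, so final labeled fractions span ≈ 0.2–0.8).  Isotopologue
distributions are exact convolutions of natural-abundance patterns for C,
H, O, S with a binomial(n_N, p) pattern for nitrogen, aggregated per
nominal mass shift (abundance-weighted centroid masses, relative-abundance
floor 1e−5).  Scans are generated on a fixed RT grid (0.2 min spacing)
with Gaussian elution (σ = 0.25 min), per-stick m/z jitter (normal, 2 ppm
SD), multiplicative log-normal intensity noise (σ = 0.05, i.e. ≈ 5% CV —
representative of strong MS1 peaks on a well-behaved modern instrument)
and 50 uniform baseline noise sticks per scan.  The interference variant
adds, per peptide, one co-eluting foreign peak at 4× the peptide's base
abundance, offset 8 ppm from one slot inside the labeled envelope region.
Everything is deterministic under the scenario seed.

What the simulator does **not** emulate — and hence what passing tests do
not demonstrate about real data: chromatographic tailing and RT drift
between runs, detector saturation and dynamic range limits, the continuum
of enrichment levels of slow in-vivo labeling (real composite envelopes are
smoother than the two-pool model), correlated ionization-efficiency drift,
and MS2/identification errors (identifications are taken as given).

## Known limitations

* **Template truncation bias.**  The ladder ends at the all-¹⁵N slot, so
  ¹³C satellites of highly labeled species fall outside the template and
  their intensity is lost from A15.  For carbon-rich peptides at 0.95
  enrichment this under-estimates RIA by up to ≈ 0.2 × (labeled fraction);
  it is the dominant error term in the simulated studies (mean |error|
  ≈ 0.04) and is inherent to the n_N + 1 template definition.
* **Single-scan estimates.**  Using one best scan per time point (by
  design) makes the RIA estimate noisier than an averaged one; with the
  strict monotonicity filter this trades recall for precision.
* **Low enrichment.**  If the new pool's enrichment is low, its envelope
  overlaps the natural one and the TP0-referenced split mis-attributes
  labeled intensity; such scenarios can be simulated but the method's RIA
  is biased there by construction.
* **Natural-envelope tail.**  Reference slots are limited to what was
  picked at TP0; natural-abundance intensity beyond the last reference slot
  at later time points is counted as labeled.  This is negligible except
  for very carbon-rich peptides with poor TP0 signal.
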