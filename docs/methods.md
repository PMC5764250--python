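# Methods

`lcmsqc` implements a longitudinal quality-control pipeline for LC-MS
proteomics instruments: targeted feature extraction from mzML QC
acquisitions, a fixed set of per-run quality metrics, and statistical
process control (SPC) of every metric series against a user-defined
high-performance baseline. This note documents the models, parameters and
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## QC samples and peptide panels

Two QC sample types are monitored. **QC1** is a low-complexity standard — a
commercial tryptic digest of bovine serum albumin with carbamidomethylated
cysteines — injected several times a day on a short gradient to track raw
instrument performance. **QC2** is a high-complexity standard — a commercial
tryptic HeLa proteome digest — injected a few times a week on a long
gradient as a system-suitability sample that mimics real workloads.

Ten BSA peptides (QC1) and fifteen HeLa peptides (QC2) are monitored; the
panels ship as a plain TSV (`src/lcmsqc/data/panels.tsv`, sequence with
inline `(CAM)` tags, panel, charge, optional expected RT) and user panels
load from the same format. Monoisotopic masses use the standard IUPAC
residue table, water 18.0105647 Da, proton 1.007276466 Da, and a fixed
carbamidomethyl delta of +57.02146 Da on tagged cysteines — the only
modification the panels need. All panel peptides default to charge 2+
(tryptic peptides of this length are predominantly doubly charged);
the charge is a column of the panel table. Expected retention times are
method-dependent configuration, not constants: the bundled table leaves
them blank, and a target without an expected RT is searched over the whole
run.

Missed cleavages are counted with the conventional trypsin rule: internal
K/R (every position but the last) not immediately followed by P.

## Feature extraction

For each target an extracted ion chromatogram (XIC) is built from the MS1
scans: per-scan summed intensity of centroids within **±5 ppm** of the
theoretical m/z, restricted to scans within **±240 s** of the expected RT.
Both tolerances are arguments everywhere they appear; window edges are
inclusive. For SRM acquisitions (no MS1 spectra) the matching chromatogram
is used instead, located by sequence annotation or Q1 m/z.

One peak per target is then detected:

* the apex *index* is the global maximum after 3-point moving-average
  smoothing (refined to the raw maximum among immediate neighbours);
* the reported apex RT is refined off the sampling grid by parabolic
  interpolation through the apex sample and its two neighbours. Without
  this, apexes are quantized to the MS1 scan interval; when run-to-run RT
  variation is comparable to that interval the longitudinal RT and RT-drift
  series become strongly non-Gaussian and their baseline standard
  deviations meaningless. Sub-sample apex estimation is standard
  feature-finder practice;
* the peak span is the contiguous region above **5 %** of the apex height,
  then extended outward while samples keep strictly decreasing, so tails
  are integrated down to baseline. Truncating exactly at the 5 % crossing
  discards ≈1.4 % of a Gaussian peak's area; the descending-tail extension
  brings integration error well under 1 % at the sampling densities used.
  The 5 % threshold is a parameter;
* area is the trapezoidal integral of *raw* intensities over the
  smoothing-determined span; FWHM is the raw-trace width at half apex
  height with linear interpolation at the crossings; observed m/z is the
  intensity-weighted mean m/z of the contributing centroids over the span;
* a peak is reported only when the apex exceeds **5×** the median nonzero
  trace intensity (any nonzero apex qualifies below 5 nonzero samples).
  This keeps baseline ripple from being reported as a feature. Absence is
  a value: a not-found target produces *no* metric record, never a zero.

Only the single highest peak per target is reported, and only the
monoisotopic m/z window is used (no isotope-envelope assembly).

## The metric set

Id-free metrics: per-peptide peak area, mass accuracy
(1e6·(observed−theoretical)/theoretical, signed ppm), per-peptide apex RT
(auxiliary) and RT drift against the previous run of the same
instrument × QC-type series, median ion injection time per MS level,
chromatographic resolution (RT₁−RT₂)/(FWHM₁+FWHM₂) for two fixed QC2
pairs (SLADELALVDVLEDK/RFPGYDSESK and FEELNMDLFR/LAVDEEENADNNTK), peak
capacity (max RT−min RT)/mean FWHM over found panel features, total ion
current (scalar sum of MS1 per-scan TIC — SPC needs one number per run;
the TIC-vs-RT trace is returned separately for carry-over inspection),
TIC slump, spectra counts by MS level, chromatogram count, and the number
of found features.

TIC slump has no published formula, only a CV accession; here it is the
final quarter's MS1 TIC sum divided by the median of the four quarter
sums (quartering configurable). A flat trace gives 1.0; values well below
1 flag late-gradient signal collapse.

Id-based metrics consume a tab-separated search-results table (PSM rows:
spectrum index, modified sequence, protein accessions, observed and
theoretical precursor m/z, charge): PSM count, distinct peptides, peptides
whose protein set has exactly one accession ("uniquely identified"),
distinct accessions, accessions supported by at least one unique peptide,
summed missed cleavages, mean/median precursor delta ppm, and the id ratio
PSMs / MS2-spectra-count. Delta ppm uses the table's own m/z values so the
metric reflects the search engine's calibration view; a disagreement above
20 ppm between the table's theoretical m/z and a recomputation is logged
as a warning. "Quantification results details" is realized as the
per-peptide area record set rather than a duplicate record.

Metrics standardized by the HUPO-PSI QC controlled vocabulary carry their
accession in qcML exports; the rest use a documented local `LCMSQC:`
namespace.

## Statistical process control

For every series key (instrument, QC type, metric, target) a **baseline**
is the mean and sample standard deviation (n−1) over the points inside a
user-chosen high-performance period, requiring at least **5** points (sd
is unstable below that). Each value is classified on
z = (value − mean)/sd:

| |z| | status | action |
|---|---|---|
| ≤ 2 | conformity (green) | continue acquiring |
| (2, 3] | warning (yellow) | preventive action |
| > 3 | nonconformity (red) | stop the instrument |

Boundaries are closed on the benign side so ties are deterministic; both
limits are parameters. A degenerate baseline (sd = 0) classifies equal
values as conformity and any deviation as nonconformity — the sd → 0 limit
of the rule. Baselines never pool across instruments, and re-baselining
after maintenance is an explicit user action, not automatic.

With a 10-point baseline the ±2·ŝd band covers only ≈91 % of future
Gaussian points (the t-distribution inflation of an estimated sd), not
95.45 %; longer baselines tighten this. The end-to-end simulations below
tally every chart point, where in-period points raise overall conformity
to ≈94–95 %.

## mzML, qcML and the store

The mzML reader is a streaming lxml parser extracting exactly the
metadata the pipeline uses; it accepts indexed and non-indexed documents,
32/64-bit and zlib-compressed arrays, normalizes RT to seconds, recomputes
per-scan TIC from peaks when absent, leaves injection time absent when not
recorded (SRM data), and centroids profile spectra by local-maximum
picking with intensity-weighted m/z. The writer emits a minimal
deterministic mzML 1.1 document (64-bit, uncompressed); identical run data
produces byte-identical files.

Runs route to series via the file-naming convention
`<YYYYMMDDThhmmss>_<instrument>_<QC1|QC2>_<freetext>.mzML` (QC token
case-insensitive) — a minimal lossless routing triple.

Metric sets export to a small self-consistent qcML-style dialect (one
`runQuality` per run, one `qualityParameter` per metric, values serialized
with full precision so read-back is exact). Persistence is a directory of
plain TSV tables — runs, metrics, baselines, annotations — diff-able and
bit-exact across reopen. Metric *values* are append-only; the status/z
columns are derived and rewritten when a baseline is (re)set, since
classification is a pure function of (value, baseline). RT drift is
recomputed for a series whenever a run is inserted, so drift always
reflects acquisition order even for late-arriving files. Annotations use a
closed vocabulary (column_change, cleaning, calibration, maintenance,
new_buffer, spray_instability, carryover_suspected, other).

## The synthetic-data generator

Every experiment runs on generated acquisitions with known ground truth.
A run recipe places each panel peptide as a Gaussian elution profile
(amplitude, sd, center) on a fixed MS1 scan grid, with ≥8 samples across
every FWHM (matching typical QC cycle-time tuning), m/z =
theoretical × (1 + ppm·1e-6) for global plus per-peptide calibration
error, interleaved precursor-tagged MS2 filler scans, Gaussian
injection-time distributions per level, multiplicative Gaussian intensity
noise plus a uniform low-level baseline, and optional SRM-style output.
Defaults: QC1 — 900 s gradient, 1.5 s scan interval, peak sd 6 s; QC2 —
6000 s, 4 s, 16 s; amplitudes staggered over roughly a decade around 10⁶;
injection times 10 ± 2 ms (MS1) and 25 ± 5 ms (MS2); 5 % intensity noise.
These are deliberately scaled-down run shapes so full experiments run in
minutes; method-faithful lengths are plain recipe fields. Fixed seeds give
byte-identical mzML.

Series recipes add run-to-run variation — global calibration jitter
(0.25 ppm) plus independent per-peptide jitter (0.2 ppm), whole-gradient
RT jitter (1 s) plus independent per-peptide elution jitter (0.5 s) — and
programmed faults: calibration steps (stepwise in ppm), RT drift
(accumulating s/run), sensitivity drops (stepwise amplitude factor), and
carry-over peaks appearing off-panel in the following run. The per-peptide
jitter components reflect that peptides respond to column and solvent
state individually, and they keep the per-peptide metric series from being
mere copies of one another.

MS2 content is structural filler: identification metrics are exercised
with directly constructed results tables, not simulated fragmentation.
The generator makes no isotope envelopes, chimeric spectra or realistic
fragments, so passing tests demonstrate the pipeline's arithmetic,
matching logic and SPC behaviour — not robustness to real spectral
complexity, co-elution or detector saturation.

## End-to-end experiments

The acceptance experiments (in `tests/test_acceptance.py`, recomputed by
`scripts/acceptance.py`) use these sizes:

* window sweeps: one-peptide runs (600 s gradient, 1 s interval, peak sd
  2 s) so a peak's full support (±4σ = 8 s) is far narrower than the 20 s
  RT sweep step — capture is then decided by the window alone;
* parameter recovery: a noiseless full QC1 run at −3 ppm, written to and
  read back from mzML;
* SPC: a 40-run QC1 series (450 s gradient), 10-run baseline, +6 ppm
  calibration step at run 20. The pipeline runs with a 10 ppm extraction
  window here: a +6 ppm fault would otherwise push peaks outside the
  default ±5 ppm matching window and make post-fault mass accuracies
  *absent* rather than nonconforming. Widening the measurement window
  (a documented parameter) keeps the fault measurable; the classification
  limits still come from the baseline alone, and the ±5 ppm default is
  verified by the window sweep.

## Known limitations

* One feature per target; co-eluting isobaric interference within ±5 ppm
  would be summed into the trace.
* FWHM of a peak truncated at the trace edge falls back to the span edge.
* The qcML dialect is self-consistent but not validated against the
  official XSD.
* Protein inference is accession-set arithmetic only (no parsimony,
  no FDR).
* The store is a flat-file design intended for single-writer use.
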