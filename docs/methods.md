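# Methods

This note records the scientific and numerical choices behind mixlib: what
the pipeline computes, which constants drive it, what the synthetic data
generator does and does not emulate, and where the design was genuinely
open.

## The curation problem

Known chemical mixtures (tens to hundreds of substances per mix) are
acquired by LC-HRMS/MS in data-dependent mode, one run per mix, ionization
mode and nominal collision energy (NCE). The goal is a curated open
spectral library: every emitted record must carry a spectrum that is
confidently attributable to exactly one compound. The pipeline therefore
chains five gates:

1. **QC prescreening** per compound x run: the extracted ion chromatogram
   (EIC) at the adduct m/z must show a peak with apex intensity >= 1e5
   counts and S/N >= 3, and at least one MS2 scan must match the precursor
   within +/-2.5 ppm and lie within +/-0.5 min of the apex. MS2 scans
   outside the RT tolerance are "RT shifted" and excluded.
2. **Fragment annotation and recalibration**: fragment peaks are assigned
   sub-formulas of the precursor ion; assigned (observed, theoretical)
   pairs train an m/z-error model that is applied before re-annotation at
   the final tolerance.
3. **Isobar resolution**: compounds of one mix within the 1 Da precursor
   isolation window of each other are grouped; retention-time anchors from
   mixes where a compound is alone in its window propagate across mixes,
   and only uniquely resolved (level 1) compounds keep their spectra.
4. **Record assembly and validation**: MassBank-format text records with
   relative intensities (1..999) and a spectral hash; spectra whose base
   peak is below 1e5 counts are rejected; every record must pass the
   pre-submission validator.
5. **Deposition projection**: a substance table (structure fields after
   cleanup) and an MS/MS annotation table with the Top-5 peaks.

## Chemistry

Monoisotopic masses are pinned to a constant IUPAC table
(`chem.MONOISOTOPIC_MASS`) so results are bit-stable. Ion m/z includes the
electron mass by default — `(M + delta - z*m_e)/|z|` — which matters at
the fourth decimal for Orbitrap-class accuracy (e.g. [M+H]+ of C10H13NO is
164.1070 with the correction, 164.1075 without); a flag disables it for
comparison with legacy software. Negative adducts gain the electron term
([M-H]- of water is 17.00329 Da).

MS-ready structure handling keeps the largest organic (carbon-containing)
component — ties broken by heavy-atom count, then exact mass, then
canonical SMILES — neutralizes formal charges where chemically possible
(quaternary nitrogen keeps its charge and remains detectable via the
formal charge), and strips stereo descriptors. Because stereo-stripped
SMILES are frequently not the registered database form, the package can
reinstate stereochemistry by matching the MS-ready skeleton against the
neutralized, stereo-stripped constitution of each component of the
original salt/mixture SMILES; the component-matching rule (canonical
constitution equality) is this package's reconstruction of the idea.

## QC estimators

The QC criteria (intensity, S/N, MS2 presence, RT shift) are standard; the
estimators are package choices:

- EIC aggregation sums all in-window centroid intensities per MS1 scan
  (window `|obs - target|/target*1e6 <= ppm`).
- Peak detection uses `scipy.signal.find_peaks` with a prominence floor of
  max(2 robust sigmas of the trace, 5% of the trace maximum, 1 count) and
  a two-sample minimum width. The floor deliberately sits *below* the S/N
  threshold of 3, otherwise a detected peak could never fail the S/N
  criterion; the width requirement suppresses single-scan spikes and the
  relative term suppresses shot-noise ripples on peak flanks.
- Baseline and noise are the median and the MAD-based sigma (MAD x 1.4826)
  of the **full** trace. Both are robust to the small fraction of scans a
  chromatographic peak occupies. An earlier variant estimated noise from
  points outside detected peak bounds, but on densely noisy channels the
  detector flags many noise bumps and excluding their cores clips the
  upper tail of the noise sample, biasing S/N upward by tens of percent;
  the full-trace estimator has no such selection effect. Its known
  limitation: a peak occupying a large fraction of the gradient (not the
  case for these sharp LC peaks) would inflate the noise estimate.
- Apex intensity and S/N are baseline-corrected (apex minus trace median).
  On a noise-free channel the noise floor is 1 count, so S/N is bounded by
  the apex counts.
- All detected peaks are retained and handed to the isobar resolver; QC
  itself never picks one. Downstream, only "QC-grade" peaks (apex and S/N
  above the thresholds) act as candidate identities.

Raising any threshold is monotone: it can only turn passes into fails.

## Annotation and recalibration

Sub-formula enumeration is an exact depth-first count enumeration with
residual-mass pruning over the precursor ion's own elements, equivalent to
exhaustive subset search (tested against one). Candidates must satisfy
RDBE >= -0.5 (allowing even-electron fragment ions) and fall within the
ppm tolerance; they are ranked by absolute error.

Annotation runs in two passes: 10 ppm before recalibration, 2.5 ppm after.
Only the 2.5 ppm screening tolerance is an external constant; the staged
scheme and the 10 ppm pre-tolerance are reconstructions of common practice
for uncalibrated fragment data. The error model is
`statsmodels` LOWESS (span 0.75, error in ppm vs observed m/z) when at
least 20 training pairs exist, otherwise a straight line; fewer than 2
pairs is an error. Predictions are clamped to the fitted range's boundary
values, and the correction is `corrected = observed * (1 - e*1e-6)`.
Within one run, calibration pairs are pooled across all annotated
compounds, mirroring per-file calibration.

Cleanup drops failpeaks (configurable), merges centroids closer than
2x the post-recalibration tolerance (intensities summed, m/z intensity-
weighted, the stronger peak's annotation kept), and applies a relative
intensity floor of 1/999 of the base peak — the smallest value
representable in the record format's relative-intensity scale.

## Isobar resolution

Groups are connected components of pairwise |delta ion m/z| <= 1.0 Da
within each mix (transitive closure: a chain of isobars closer than the
window each joins one group even if its extremes differ by more). The
resolver iterates to a fixpoint:

- a compound alone in its group with exactly one QC-grade peak is
  confirmed (level 1, `alone_in_mix`) and anchors its RT globally;
- anchored compounds claim the nearest peak within the RT tolerance
  (default 0.5 min, shared with QC) in every other mix
  (`anchored_elsewhere`);
- if exactly one unclaimed peak and one unanchored member remain, the
  member is confirmed `by_elimination` — which may anchor it for further
  mixes, hence the fixpoint;
- a peak claimed by two anchors (co-elution) demotes both claimants to
  level 3 in that mix: safety over coverage;
- members with peaks left but no unique mapping are level 3 (`ambiguous`);
  this includes the fewer-peaks-than-members case (e.g. two candidates,
  one peak), where *some* compound is present but the identity is unknown;
- no peak at all means `not_detected`.

The first rationale that confirms a compound-mix pair is kept across later
fixpoint passes (so the worked two-mix example reports `by_elimination`,
not the re-derived anchor claim), but demotions computed at the fixpoint
win over earlier confirmations. Only level-1 spectra survive
`filter_records`; every exclusion is logged.

## Records, SPLASH, deposition

Records are flat `TAG: value` text files terminated by `//`, modelled on
the current MassBank record layout; m/z is written with 4 decimals,
intensities as integer counts, relative intensities as
`max(1, round(999*I/Imax))`. Parsing preserves unknown tags in order, so
`parse(write(r))` is exact and re-serialization is bit-identical.
Validation checks mandatory fields, the accession shape
(`MSBNK-<contributor>-<code>`), peak-count and sortedness, the relative-
intensity scale, formula/exact-mass agreement within 5 ppm, and recomputes
the spectral hash. Accession serials are allocated sequentially in a
deterministic record order (compound, mix, mode, CE); the numbering within
a contributor prefix is internal.

The spectral hash follows the published SPLASH block layout for MS spectra
(`splash10-` + 4-char base-36 top-ten hash + 10-digit wrapped intensity
histogram + 20 hex chars of the full-spectrum SHA-256), with intensities
normalized to the base peak (0..999) before hashing so the hash is
scale-invariant, and m/z scaled by 1e6 and rounded. No reference SPLASH
implementation is distributable with this package, so the exact rounding
and separator conventions are pinned here and cross-checked in the test
suite against an independently coded duplicate; hashes are stable and
collision-resistant for this library but are not guaranteed bit-identical
to other SPLASH implementations.

Deposition rows carry the agreed display field list (accession, authors,
instrument, instrument type, MS level, ionization mode, ionization,
collision energy, fragmentation mode, column name, retention time,
precursor m/z, precursor adduct, license, publication, SPLASH, Top-5
peaks) plus the structure block (name, SMILES, InChI, InChIKey); accession
and SPLASH are the hyperlink-bearing fields. Top-5 keeps the five most
intense peaks, ties resolved toward lower m/z. Substance cleanup removes,
in order and with per-reason counts: "N/A"/empty structures, SMILES with a
`*` wildcard atom, bad-list SMILES (exact string match), and duplicate
(SMILES, InChI, InChIKey) triples after whitespace normalization; the
counts plus the output length always equal the input length, and cleanup
is idempotent.

## Synthetic data generator

The generator defines the study conditions for every test:

- **Design**: ten mixes named 499-508 with sizes
  95/95/95/95/185/185/365/365/95/365; mix 503 contains the replicate set
  of mix 499, mix 505 contains 270 new substances plus the replicate set
  of 499. Compounds are valid homologous-series structures (alcohols,
  acids, amines, amides, nitriles, esters, diols, aromatics, thiols,
  chloro/fluoro compounds, sulfonamides) packed so that within-mix ion
  m/z gaps exceed 1.2 Da — no accidental isobars — before requested
  same-formula isobar pairs are planted on top, with or without a
  disambiguating solo mix.
- **Runs**: MS1 scans every 0.02 min over 1.0-15.5 min (a ~1.2 s Orbitrap
  cycle), Gaussian chromatographic peaks with sigma 0.05 min, apex
  intensities uniform in [2e5, 5e6] counts, +/-1% multiplicative shot
  noise, ~10 spurious baseline centroids per scan (exponential
  intensities, scale 300). DDA MS2 scans are inclusion-list driven: three
  scans around each member's apex, precursor at the observed (error-
  shifted) ion m/z, 1 Da isolation width, NCE levels {15,30,45,60,75,90}
  (tests use the first two to keep runtimes small).
- **Mass error**: a planted ppm-vs-m/z curve applied to all observed m/z;
  the default, 0.8 + 0.0015*(m/z - 100) ppm, stays inside the 2.5 ppm
  screening window across the simulated mass range while remaining
  recoverable by the recalibration stage. Recovery tests plant constant
  +5 ppm and steeper linear curves directly.
- **Fragments**: per compound and CE, a random subset of true sub-formulas
  of the precursor ion (RDBE >= -0.5, m/z >= 50) plus the precursor ion
  itself; intensities favour low-mass fragments at high NCE through a
  Gaussian weight in the m/z fraction. This is deliberately non-physical:
  it provides known-true annotations, not realistic fragmentation
  chemistry.
- **Planted QC violations**: `intensity` forces the apex to 5e4;
  `snr` adds a dense elevated baseline (offset 3 sigma, clipped Gaussian
  jitter, sigma = apex/2.5) to the compound's m/z channel outside the
  peak region, so the measured S/N is ~2.5 deterministically; `ms2_present`
  suppresses MS2 triggering; `rt_shift` moves every MS2 scan 0.7 min past
  the apex (such compounds' RTs are capped so the shift fits the
  gradient).
- **Determinism**: every random draw comes from `numpy` generators seeded
  from the dataset seed plus a CRC of the run tag, so a fixed seed
  reproduces all mzML files byte for byte.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: profile peak shapes and centroiding artefacts,
isotope patterns, adducts other than the protonated/deprotonated species,
in-source fragmentation, co-eluting matrix interference, retention-time
drift between runs, and realistic fragmentation spectra. The pipeline's
correctness on these synthetic conditions demonstrates the logic of the
gates, not instrument-grade performance.

## Problem sizes in the test suite

The suite exercises: the full ten-mix design layout (compound generation
only), a 50-compound single mix with ten planted violations for QC
exactness, the two-mix worked isobar example at two CE levels, and a
3-mix x 8-compound x 2-CE dataset for the end-to-end, record-integrity and
byte-determinism checks. These sizes keep the whole suite under a minute
while covering every stage contract; scaling up only increases counts, not
code paths.

## Known limitations

- The fewer-peaks-than-members case is reported as level 3 for all
  members rather than attempting partial assignment.
- Recalibration pools pairs per run; per-compound curves are not fitted.
- The spectral-hash dialect is internally consistent but not verified
  against external SPLASH implementations (see above).
- Compound metadata enrichment (synonyms, identifiers) is expected to be
  provided offline in the compound list; no web services are queried.
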