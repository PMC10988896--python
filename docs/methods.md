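# Methods

This note documents the models behind the simulator, every constant that
matters, the design decisions taken where the behavior of real hardware and
vendor software is not public, and what the synthetic experiments do and do
not show about real instruments.

## Sample model

**Species.** Every analyte is a peptide species: sequence, charge (2–4),
label channel (light / Lys8 / Arg10), on-column amount (fmol), elution apex
and peak width. Heavy and light members of a pair share everything except
label, amount and m/z; the precursor gap is exactly the label mass over the
charge (Lys8 = 6×(¹³C−¹²C) + 2×(¹⁵N−¹⁴N) = 8.014199 Da, Arg10 = 10.008269
Da). Monoisotopic masses come from the standard residue table with fixed
carbamidomethyl-cysteine as the only modification.

**Elution.** Symmetric Gaussian flux, default σ = 6 s (~30 s base width):
`flux(t) = A·exp(−(t−apex)²/2σ²)` with `A = amount·IONS_PER_FMOL/(σ√2π)`,
so the time integral equals `amount × IONS_PER_FMOL`. `IONS_PER_FMOL = 5e6`
detected charges per femtomole folds ionization, transmission and detection
efficiency into one constant; it sets the absolute scale on which AGC
targets and trigger thresholds act. A symmetric peak is enough here because
the triggering phenomenology (clipping) only needs a rising edge.

**Isotope envelopes.** Averagine-composition envelopes (4 peaks by default),
computed by exact polynomial convolution of the per-element isotope
abundance vectors and normalized; peaks are spaced 1.00336/z Th. The first-
and second-isotope ratios agree with the closed-form combinatorial expansion
to machine precision (tested).

**Fragments.** Each peptide declares up to six singly charged y ions
(y3 upward), with relative intensities drawn once per sequence from a
Dirichlet(2) and frozen — identical for the two label channels. y ions only:
the declared trigger fragments must carry the C-terminal label so that the
heavy→light fragment shift used in validation and light-channel extraction
is well defined (b ions are label-free and would be shared peaks). The
`fragment_mz` primitive itself supports both b and y series.

**Background matrix.** A complex digest is emulated statistically: random
tryptic-like sequences (length 8–16, C-terminal K/R, charge 2–3, precursor
within the scan range), apexes uniform over the gradient, abundances
log-normal with σ = 1.5 decades truncated at ±2σ around a 0.5 fmol median —
spanning > 4 orders of magnitude. This reproduces the *mechanisms* of matrix
interference (AGC stealing, chimeric MS2, occasional dominant co-eluters),
not the composition of any real digest.

## Instrument model

**Accumulation.** `injection_time = min(max_IT, AGC_target/total_flux)`
where total flux is everything entering the isolation window(s) (whole scan
range for MS1). A peak's expected collected charge is
`flux_species × envelope_fraction_isolated × fragment_share × IT`. When
accumulation is AGC-limited, total collected charge caps at the AGC target,
so abundant co-isolated species suppress scarce ones — the central reason
wide DIA windows lose low-abundance fragments.

**Timing.** Scan duration = `max(IT, transient) + 0.005 s`, with transient
linear in resolving power: 0.016 s at 7.5 k up to 0.256 s at 120 k (0.064 s
at 30 k). These are declared model constants, not fitted vendor values. The
run clock advances by every scan's duration; the scan log conserves time
exactly.

**Noise.** Peak charges are Poisson-sampled, multiplied by a 5 % log-normal
jitter; m/z is perturbed by Gaussian error with σ = 2 ppm. Each scan carries
a noise floor = 5 charges (electronic) + 60 charges·s⁻¹·Th⁻¹ × isolation
width × IT (diffuse chemical background standing in for the many unmodeled
tiny peptides); peaks below the floor are censored. A 15 Th DIA window
therefore has a ~5× higher floor than the two 1.4 Th MSxPRM windows — one of
the two mechanisms (with the longer 116 ms vs 54 ms injection) behind the
sensitivity gain of triggered scans. With `noise=False` the instrument is
exactly linear (no sampling, no censoring, zero floor), which the linearity
and status tests rely on.

**AGC mapping.** Normalized "1000 %" AGC targets are mapped to absolute
charges: 3e6 for MS1, 1e6 for MS2/validation/MSxPRM scans.

## Acquisition engine

One DIA cycle tiles the scan range half-open with `ceil((high−low)/width)`
MS2 windows (400–1210/15 → 54) and inserts an MS1 scan every 18 MS2 scans
(→ 3 per cycle). In hybrid mode every MS1 scan is checked against the watch
list; a target is a candidate when it is inside its RT window (closed
interval), not dynamically excluded, and its heavy precursor m/z matches a
peak within 10 ppm at or above the intensity threshold. Candidates are
serviced immediately, in ascending precursor m/z, each as: fast validation
MS2 (7.5 k resolution, 10 ms max IT, 1.4 Th on the heavy precursor; passes
when ≥ 4 of the declared fragments match within 10 ppm above the scan
floor), then one MSxPRM scan (two 1.4 Th windows on heavy and light, 30 k,
116 ms max IT), then exclusion for 5 s. One validated trigger yields exactly
one MSxPRM scan, so a peak is sampled about every exclusion period. All
decisions are logged (candidate → validated/rejected → acquired).

Defaults the vendor tool does not disclose, declared here and configurable:
validation scan parameters ("fast" is all that is public), 4-of-6 minimum
validated fragments, MS1-based trigger detection (3 checks per cycle),
per-target thresholds defaulting to a global 5e4.

Trigger threshold: the method is documented with thresholds of 1e5 or 5e4;
the package defaults to 5e4 because on this model's charge scale a 100 fmol
heavy reference apexes near 1e5–3e5 MS1 charges, and the quantification
contract (≥ 3 points per peak) needs the trigger to arm on the rising edge,
as it does on the real instrument.

**Stand-alone modes.** `dia` runs cycles with no watch list (a hybrid run
with an empty panel is scan-for-scan identical — tested). `prm` replaces
triggering with a time-driven schedule: one MS1 survey scan, then an MSxPRM
scan for every target whose RT window contains the clock and whose
per-target resampling interval (the exclusion time) has elapsed. A schedule
whose worst-case concurrent demand (max concurrency × MSxPRM duration + MS1)
exceeds the sampling interval raises a `ScheduleError` up front rather than
silently dropping scans.

**Peak clipping.** Triggering requires the rising heavy signal to cross the
threshold, so the first MSxPRM scan always starts after elution start, later
for higher thresholds, and the captured light area is monotone non-increasing
in the threshold. This emergent truncation of the leading edge — and its
growth with panel size as MS1 checks space out under triggered-scan load —
is the simulator's account of why triggered quantification CVs degrade with
target count.

## Scheduling analysis

RT windows are seconds internally; the target-list parser accepts `_min`
column headers and converts. Concurrency profiling is a sweep line over
window endpoints with closed-interval semantics (start events before end
events at ties), verified against a dense-grid counting oracle on random
instances. The duty-cycle report assumes worst case — every active target
fires once per exclusion period, each firing costing one validation + one
MSxPRM scan — and reports per-bin DIA/triggered time fractions (capped at
the total budget) plus the implied stretched cycle time.

## Quantification

XICs take one point per matching scan (summed intensity within the ppm
tolerance, zero when absent). Peak integration is trapezoidal over the
contiguous region around the apex above the boundary (the censored noise
floor already removes sub-floor points; an explicit 3× floor boundary is
available). A pair is `quantified` when both channels integrate from ≥ 3
MSxPRM points; `below_LOD` when only the heavy does; `missing` when the
heavy reference never produced 3 points. Because both channels are measured
in the same scans with the same injection time, the light/heavy area ratio
is an unbiased amount ratio, independent of shared peak-shape parameters
(tested: changing σ for both channels moves the ratio < 1 %).

The DIA comparison arm is a deliberately simple stand-in for a
spectral-library search: a peptide is DIA-detected when its precursor gives
≥ 3 MS1 points and ≥ 3 of its fragments each give ≥ 3 points in the DIA
window containing the precursor. DIA has no spike-in to certify absence, so
its undetected cells are `missing`, never `below_LOD`.

Calibration fits least squares on log10(nominal) vs log10(ratio) over
quantified points (≥ 3 levels, otherwise flagged unfit). The LOD is
detection-based — the smallest nominal level quantified in at least half its
replicates — matching how dilution series are read in practice; a blank+3 sd
style definition was considered and not used because the simulator's blanks
are exact zeros. Below-LOD cells report as `< {LOD} fmol/μl`. Protein rollup
is the mean of quantified peptide amounts; a protein with only below-LOD
peptides inherits `below_LOD`. Completeness is the percentage of
`quantified` cells, optionally counting `below_LOD` as informative.

## Experiment presets and problem sizes

Presets are seed-reproducible end to end (byte-identical TSVs). They use
compressed gradients with background density chosen so the co-elution load
per scan matches a full-length run (~15–35 concurrent background species):

- **dilution_series** — 24 pairs, light 100/10/1/0.1/0.01 fmol against
  100 fmol heavy, 3 replicates × 3 modes, 300 s gradient, 200 background
  peptides.
- **target_count_stress** — one sample carrying 179 pairs (100 fmol light
  and heavy), panels of 60/120/179 triggers, 3 replicates, 960 s gradient.
  The longer gradient keeps RT-window concurrency near the real method's
  (≤ ~36); at 3× compression the spike panel itself would consume the MS1
  AGC budget, a regime the real experiment never entered.
- **marker_panel** — 30 pairs over 12 synthetic samples × 2 technical
  replicates, light abundances log-uniform over 4 decades with 20 %
  structural zeros (so all three statuses occur), hybrid and DIA matrices
  side by side, 240 s gradient.

On one CPU the three presets take well under a minute each.

## What passing tests do and do not show

The generator reproduces the *mechanisms* the acquisition strategy exploits
— co-elution of the heavy/light pair, matrix masking, duty-cycle pressure,
threshold-delayed triggering — with exactly known truth, so the suite can
assert quantification accuracy (≤ 10 % median error above 10× LOD), status
semantics, and the directional orderings (triggered detection ≥ DIA at low
levels; hybrid completeness ≥ DIA; CV fraction degrading with panel size).
It does not emulate real chromatography (tailing, drift), real digests,
library search or FDR control, and absolute numbers (protein-group counts,
completeness percentages, CV magnitudes) are properties of the synthetic
conditions, not predictions for any instrument.

## Known limitations

- Nominal spike amounts are treated as exact truth; real stocks are
  approximate.
- Fragment intensity patterns are Dirichlet draws, not fragmentation
  physics; interference between isobaric fragments is possible but rare at
  the simulated peptide density.
- The validation scan model (resolution, IT, 4-of-6 rule) is a declared
  stand-in for undisclosed vendor logic.
- No profile peaks, charge-state deconvolution, or detector physics beyond
  linear accumulation with AGC saturation.
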