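# Methods

`diawin` implements a SWATH-style DIA lipidomics workflow around four
ideas: build an annotated MS/MS library from iterative DDA injections;
design variable quadrupole isolation windows so that precursor density
is balanced across windows; extract MS1 and per-fragment MS2 peak areas
for every library entry from the DIA data; and score the result with
the QC, fragment-selection and differential-abundance statistics that
such studies report. A synthetic-run simulator provides ground truth
for every stage.

## Run model and mzML

Spectra are centroided, retention times are minutes everywhere in the
API (the reader converts second-valued scan times), and every MS2 scan
must carry its isolation-window bounds. A run is classified DIA when at
least two MS2 scans share identical precursor bounds wider than 2 Th;
anything else is DDA. The mzML layer is self-contained: the reader
handles plain/indexed mzML, 32/64-bit float arrays and zlib
compression; the writer emits uncompressed 64-bit arrays, which makes
simulator output round-trip bit-for-bit on m/z, intensity and window
bounds — the property the I/O tests pin down. Vendor formats,
profile-mode data and ion mobility are out of scope.

## Signal processing

XICs are built per scan as the summed intensity within ±tol of the
target m/z (defaults: 0.005 Th for MS1, 0.01 Th for MS2). Peak picking
finds local maxima above a noise floor (default 0) and walks outward to
the nearest valley or the first at/below-floor point; apex and valley
decisions are made on a 3-point binomial smoothing of the trace so that
detector noise does not truncate flanks, while the reported area is the
trapezoidal integral of the *raw* trace — integration is therefore
exactly linear in intensity, and no baseline is subtracted. A peak
needs at least 3 points; the classical ≥10-points-per-peak guidance is
treated as an acquisition design target, not a detection filter.

MS1 features come from greedy mass traces: the most intense unclaimed
centroid seeds a trace whose running intensity-weighted centre claims
at most one centroid per scan within ±tol; each chromatographic peak on
a trace becomes a feature. No deisotoping or adduct grouping is done,
deliberately: the window designer needs the density of everything that
loads the quadrupole, and isotopes do. The exact feature-detection
algorithm behind the original workflow is not public; this mass-trace
scheme is the package's own stand-in and is only required to be
*adequate for density estimation*, which the recovery tests
(≥48/50 species located within 0.005 Th / 0.05 min on clean runs)
support.

## Variable window design

Each feature's density is the count of features within
`density_radius` of its m/z (default 2.5 Th ≈ an isotope envelope plus
near-isobars; results are insensitive at the 10–100 Th window scale).
Density ignores RT because the quadrupole schedule is RT-independent —
every window is acquired every cycle.

Partitioning walks features in ascending m/z, accumulating density, and
cuts when the running sum reaches (density remaining)/(windows
remaining); the cut lands on the midpoint between consecutive feature
m/z values (choosing the side that leaves the sum closer to the target)
and is clamped so both the current window and the remaining tail can
respect the `[min_width, max_width]` limits. The last window ends
exactly at `mass_high`; with no features the partition is uniform. A
feature exactly on a boundary belongs to the lower window — the same
tie rule `assign_window` uses, so density accounting and channel
assignment can never disagree. Extension adds ±`extension` (default
0.5 Th) to every core, giving each adjacent pair an overlap of exactly
`2·extension`.

The greedy sweep is a heuristic, not a global optimizer. On small
clustered layouts it attains the exhaustive variance-minimizing optimum
(the test-suite oracle enumerates all feasible boundary placements on
the midpoint grid), but adversarial layouts exist where it is slightly
suboptimal; "approximately equal summed density" is the design goal,
and the balance tests bound the max/min window-density ratio at 1.5 on
continuous inputs.

## Spectral library

Consensus spectra are built from iterative DDA injections by grouping
MS2 scans on (precursor ±ms1to1, RT ±rt_tol); fragment peaks merge at
ms2to1 resolution with the **median** intensity across injections —
robust against DDA's habit of triggering on peak flanks. The consensus
precursor m/z is the total-ion-weighted mean.

Matching scores are cosine similarity on square-root intensities over
the union of greedily (closest-m/z-first, one-to-one) paired and
unpaired peaks within 0.01 Da. The score's functional form is a package
choice — only the 0.5 acceptance threshold is externally fixed — and it
is symmetric, 1 on self-matches and 0 on disjoint spectra. Annotation
requires precursor Δ ≤ ms1to1 (0.005 Th), RT Δ ≤ RT_shift when the
reference has an RT, score ≥ 0.5 and ≥ min_peaks (1) matched fragments.
Score ties resolve to the **last** entry in the reference list; this
mirrors the established library convention deliberately (reference
libraries list constituents of one sum composition in ascending order,
so the last entry wins), and a `tie="first"` switch offers the
alternative. Only [M+H]+ / [M+NH4]+ survive adduct filtering in
positive mode and [M−H]− / [M+HCOO]− in negative; duplicates collapse
per (sum composition, adduct, polarity) keeping the best score, ties to
earliest RT.

`RT_shift` units are not externally defined; the package interprets
them as **seconds** by default (10 s for DDA search, 20 s for DIA
extraction) with `rt_shift_units ∈ {sec, min, scans}` exposed.

Lipid shorthand follows `CLASS[-P|-O] C:D(;xO)?(/C:D(;xO)?)*` with
legacy sphingoid prefixes d/t/m mapping to 2/3/1 hydroxyls and isotope
labels (`-d9`) tolerated and dropped from sum compositions. The sum
composition collapses chains to total carbons:double bonds
(`SM 30:1;2O/2:0` → `SM 32:1`); hydroxyl counts are carried internally
but not displayed, matching how such results are reported. Chain-less
names (e.g. `COH-d7`) pass through opaque.

## Targeted DIA extraction

Per entry: the precursor XIC at ±ms1to1 is picked first, choosing the
detected peak nearest the library RT within ±RT_shift. Fragment XICs
are extracted only from the single window whose **core** contains the
precursor (never summed across the overlap, avoiding double counting)
and must co-elute with the chosen MS1 apex within ±RT_shift/2. The
co-elution gate is the package's answer to DIA's severed
precursor–product link; whether to pick fragments independently was an
open design choice, and co-elution was chosen and is documented here.
Channels with no qualifying peak stay null (not zero). A second pass
force-integrates nulls over RT ± RT_shift with a `filled` flag —
detected areas are bit-identical between the `quant_all` (detected
only) and `quant_fill_all` (complete) tables. No saturation correction
is applied at extraction; saturation is handled downstream by the
linearity volume cut-off.

## Statistics

* **RSD** = 100·sd/mean with the sample (n−1) sd, computed on
  *unfilled* QC values only so fill cannot flatter reproducibility;
  fewer than two values → non-quantifiable. Categories: <20%, 20–30%,
  >30%, non-quantifiable. Two median conventions are emitted side by
  side — over channels passing the 30% gate, and over all quantifiable
  channels — because both appear in this literature's summary tables.
* **Fragment selection**: squared Pearson correlation of each fragment
  against its MS1 precursor across samples; the best fragment has the
  highest R², ties to lower QC RSD then higher median area. Zero
  variance makes R² undefined and fails every ≥ gate.
* **Dilution linearity**: per-channel R² of mean area vs injection
  volume, restricted to volumes ≤ 4 µL because detector saturation
  above that volume would otherwise corrupt the fit.
* **Retention filter**: an entry enters differential analysis iff its
  MS1 QC RSD < 30% (strict), at least one fragment's QC RSD < 30%, and
  that fragment's R² vs MS1 over all study samples > 0.8. Filled values
  participate in the R² (fill precedes this step in the workflow
  order); RSD never uses them.
* **Representative readout**: per lipid, polarities merged on the sum
  composition string, the passing channel with the lowest QC RSD.
* **Differential abundance**: fold change is the ratio of arithmetic
  group means (matching how fold-change thresholds are quoted on raw
  abundances); the test is a two-sided Welch t on log2 areas — chosen
  for unequal variances at n≈5, with Mann–Whitney a documented
  alternative — with a 1e-12 variance floor (flagged) for degenerate
  groups; FDR control is the package's own Benjamini–Hochberg step-up,
  cross-checked against statsmodels at 1e-12 in the tests. Significance
  = |FC| > 2 in either direction AND q < 0.05.
* **Median centring**: per lipid, log2(area / median across samples);
  row medians are exactly zero. No internal-standard normalization is
  performed anywhere.

## Synthetic data

The simulator emulates a ~15.8 min reversed-phase lipid gradient:
species elute as Gaussians (σ = 0.04 min, base width ≈ 0.16 min) at
class-typical RTs, precursor m/z comes from a class-dependent Gaussian
mixture on 300–1000 Th weighted TG > PC > SM > LPC > Cer > DG (so
density is non-uniform, the regime variable windows exploit),
abundances are log-normal (median 2×10⁵ counts, σ = 1), and each
species carries 1–10 fragments in 50–1000 Th whose yields sum to ≤ 1.

Noise has two scales, both mean-one log-normal:

* **per-point detector noise** (`noise_cv`) applied to every centroid
  when raw runs are rendered — it partially averages out over the
  ~30 points of a peak, so 3–5% point noise yields ~1% area noise;
* **per-channel, per-injection technical noise** (`ms1_cv`, `ms2_cv`)
  used when quantification matrices are generated directly
  (`simulate_two_group_matrix`) — this is what QC RSDs measure.

DIA cycles are one MS1 scan plus one MS2 scan per window at 20 and 40
spectra/s (cycle = 1/20 + n_windows/40 s); a species' fragments land in
every window whose *extended* bounds contain the precursor, so overlap
species appear in two windows. DDA runs use 1.6 s cycles with top-5
triggering above 200 counts, active exclusion for 0.08 min after one
repeat, and an iterative exclusion list (±20 ppm, ±0.2 min) carried
across injections. Saturation, when enabled, is a smooth
`ceiling·tanh(I/ceiling)` clamp so linearity degrades gradually rather
than truncating. Identical seed + design gives byte-identical mzML.

What the simulator does **not** model: isotope envelopes, in-source
fragmentation, chimeric MS2 beyond window co-isolation, ion
suppression, RT drift between runs, and electronic baseline. Passing
tests therefore demonstrate correctness of the algorithms under the
stated noise model, not robustness to every artefact of real data.

### Problem sizes

Tests and examples compress elution into a 1–4 min RT span and use
25–200 species so that a full run renders in seconds; the physics
(points per peak, windows, rates, widths) is unchanged by the
compression. The DDA scheduler studies use a 100-species catalog
compressed into ~0.4 min: a desk-scale catalog spread over the full
gradient has almost no precursor competition, whereas a real plasma
extract keeps dozens of features co-eluting at all times, and the
compression restores that regime (≈50 co-eluting species against 30
top-5 slots per peak width). Power studies (150 null + 50 changed
lipids, n = 5+5, 6 QC, 20 seeds) run at matrix level: channel areas are
drawn directly from the analytic peak areas with technical noise, which
is statistically equivalent to rendering and re-extracting runs — the
extraction layer recovers analytic areas to within a few percent, as
the raw-run recovery tests show — at a small fraction of the cost.

## Known limitations

* The greedy window partition can miss the global density-balance
  optimum on adversarial layouts (documented above).
* Spectral deconvolution of DIA MS2 into pseudo-DDA spectra is not
  implemented; identification rests entirely on the DDA library.
* The last-entry tie rule reproduces an upstream convention that is
  arguably arbitrary; `tie="first"` is provided.
* p-values from the Welch/BH chain depend on the (unstated upstream)
  test choice; other reasonable tests will give slightly different
  significant sets near the thresholds.
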