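# Methods

This note documents the models, conventions and numerical choices behind
lipidkit, what the synthetic generators do and do not emulate, and the
design decisions taken where the underlying analysis conventions were
genuinely open.

## Annotation model

Species are represented at sum-composition level: a class, total acyl
carbons C and total double bonds d (`PC 34:1`). Elemental formulas follow
head-group + acyl arithmetic per class (diacyl phosphatidylcholine
C:d → C_{C+8}H_{2C+16−2d}NO8P, and analogously for LysoPC, PE, PI, TAG,
DAG, CE, SM, Cer, FA); each formula loses two hydrogens per double bond.
Monoisotopic element masses are pinned to a constant table inside the
package (CODATA/AME rounded to 1e-6 Da) so theoretical masses are
reproducible; the test suite cross-checks them against an independent
element-mass library. Isomer resolution below sum composition (acyl
positions, sn-1/sn-2, ether subclasses) is out of scope.

Annotation keeps at most one candidate per peak: among all
(species, adduct) pairs inside the tolerance window, minimal
|observed − theoretical| wins; ties within 1e-6 Da break toward fewer
double bonds, then lexicographic species id — a deterministic refinement of
the "single candidate per peak" convention. Two tolerance modes exist
because imaging and LC-MS practice differ: absolute (default 0.5 Da) and
relative (default 5 ppm). The reported mass error deliberately keeps the
*observed* m/z in the denominator; the convention is nonstandard but is
followed as printed in the protocol it re-implements, and the asymmetry
is second order (bounded by |Δm|/m per swap).

MS/MS confirmation is a simplified class-diagnostic check (the vendor
pipelines' full scoring is unpublished): a candidate is confirmed when its
class's diagnostic product ion (184.0733 for choline-head-group classes)
or neutral loss (141.0191 for PE; a representative acyl loss for TAG) is
present within 0.01 Da at ≥ 1% of the base peak. Unconfirmed candidates
are retained as MS1-only annotations with an explicit flag rather than
discarded, so downstream counts are auditable.

## Natural-abundance correction and flux ratios

The correction model is carbon-only binomial: with j tracer-derived labels
on an n-carbon analyte, the probability of observing M+i is the binomial
probability of i−j natural 13C among the remaining n−j positions at
p = 0.0107. Contributions of 2H, 15N, 17O/18O are ignored — for fatty-acid
pentafluorobenzyl derivatives read at M+2 resolution they are below 0.1%
and would not survive the unit-mass binning anyway. Deuterated internal
standards live at shifted masses and are treated as separate analytes; no
cross-correction is attempted.

Inversion uses the exact lower-triangular solve when it yields no negative
entry and otherwise non-negative least squares (`scipy.optimize.nnls`),
followed by clipping at zero and renormalization to unit sum; this keeps
fractions valid under measurement noise at the cost of a small bias near
the boundary. Ratios M+2/M+0 and M+4/M+0 are computed from *corrected*
fractions by default (whether the original readouts were corrected first
is unstated; both routes are available since correction is a separate
call). A zero M+0 fraction makes ratios undefined; they are reported as
missing with a reason, never as infinity.

Two internal-standard rule sets ship because the source protocols list two
different deuterated triples: the default maps C ≤ 18 → 16:0-d31,
C = 20 → 20:4-d8, C = 22 → 22:6-d5; the alternative triple
(16:0-d31, 18:1-d5, 20:4-d8) is selectable, with length ranges assigned by
proximity. The discrepancy is preserved as configuration rather than
resolved. Analytes matched by no rule pass through unnormalized with a
flag; a zero-intensity standard rejects the sample.

## Saturation profiling

"Relative double-bond quantification" is implemented as within-class
fractions per sample (class member abundances at each double-bond count
divided by the class total), making profiles invariant to per-sample
scaling; whether the original figures show fractions or
standard-normalized absolute signal is not printed, so the choice is
flagged here. Saturation bins are SFA = 0, MUFA = 1, PUFA ≥ 2 double
bonds, applied to sum-composition totals. Fold-changes default to log2
(the lipidomics convention; the base is configurable) with a pseudo-count
of half the smallest nonzero abundance so dropouts stay defined.

## Differential statistics

The default test is the unpaired pooled-variance Student's t (the
"multiple t-tests" convention of common statistics software), Welch
selectable; species-level tests run on log2-transformed abundances,
class-level tests on the provided scale — both configurable, since the
original scale choice is unstated. Degenerate features (zero variance in
both groups, equal means) return t = 0, p = 1.

The FDR procedure is the two-stage adaptive linear step-up: stage 1 is
Benjamini–Hochberg at q′ = q/(1+q) with r₁ rejections; r₁ = 0 rejects
nothing and r₁ = m everything; otherwise stage 2 reruns the step-up at
q′·m/(m−r₁). Adjusted values invert the stage-2 threshold monotonically
(adj₍ᵢ₎ = min over j ≥ i of p₍ⱼ₎·(1+q)(m−r₁)/j, clipped to 1), so
"adjusted ≤ q" reproduces the rejection set exactly; because the procedure
is adaptive these adjusted values depend on q, which is recorded in
outputs. The implementation is verified against a brute-force step-up
oracle and against statsmodels' two-stage variant. Volcano tables clamp
q = 0 to the smallest positive normal float for the −log10 display and
flag the clamp.

The immunoreactivity (H-)score is grade (0–3, integer) × percent positive
(0–100), range 0–300, exactly bilinear.

## Imaging

Processing order is fixed: per-pixel TIC normalization (to percentages
summing to 100), then marker extraction, then ROI statistics — matching
the stated order of the imaging protocol; raw-intensity marker images are
additionally emitted because it is ambiguous which scale the original ROI
tables used, and both are labeled in the output. Zero-TIC pixels become
missing values and are counted, not silently dropped.

Peak detection thresholds the baseline-subtracted mean spectrum (spectrum
minus its median) at SNR × noise; the noise estimator is 1.4826 × MAD of
the mean spectrum by default (robust to sparse peaks), with the standard
deviation of a user-specified signal-free band selectable. The baseline
subtraction makes the SNR comparison meaningful on spectra with a nonzero
flat background, which a raw-intensity threshold would saturate. Grouping
is single linkage: adjacent candidates closer than 0.5 Da merge
transitively; marker centers are intensity-weighted means. Marker images
take the maximum intensity within ±0.05 Da.

ROI statistics: mean per mm² divides the ROI sum by n_pixels × pixel
area, with the pixel pitch (default 60 µm acquisition spot) as
configuration; SD is the population SD (a single-pixel ROI has SD 0);
quartiles use linear interpolation (numpy's default inclusive
convention), pinned here because the original software's convention is
unpublished. Baseline subtraction, spectral alignment across pixels,
co-registration with histology, and in-source-fragmentation modeling are
out of scope. imzML ingest (continuous mode) is optional via pyimzml;
otherwise grids travel as axis CSV + pixel × bin CSV + JSON header.

## Synthetic data

The generators define the study conditions used throughout the tests:

* **Lipidome tables** — log-normal abundances (per-species baselines
  around 1e5 arbitrary units with 0.5 log-SD spread; within-condition
  CV 20%, the typical biological variability of replicate lipidomics),
  5 samples per condition, 9 classes × 4 species spanning SFA/MUFA/PUFA
  compositions. Effects are multiplicative on the mean; bin-level effects
  (class, saturation) override whole-class effects. Three versioned
  presets plant the qualitative signatures the pipeline is meant to
  detect: `fig1_km` (PC, TAG, SM, PE, CE 2× up; LysoPC, DAG 0.5×),
  `fig1_egfr` (PI 2×, TAG 0.5×, CE 2×, DAG 0.5×), and `fig4_fasni_km`
  (LysoPC and DAG 2×, PUFA-PC 2×, SFA/MUFA-PC and SFA/MUFA-TAG 0.5×,
  PUFA-TAG explicitly unchanged). Magnitudes are round defaults (2×,
  0.5×); the source figures report directions, not effect sizes.
* **Isotopologue envelopes** — forward binomial convolution of planted
  fraction vectors supported at even M+n (two-carbon acetate units), with
  multiplicative log-normal channel noise (default 5%).
* **Ion images** — a tumor ellipse (axes 10 × 7 px in a 40 × 30 grid,
  60 µm pixels) with tumor-elevated SFA/MUFA-PC markers and a
  stroma-elevated PUFA-PC marker at their protonated theoretical m/z on a
  0.1 Da axis; optional log-normal or Poisson pixel noise and per-pixel
  TIC variation.
* **Peak lists** — theoretical adduct m/z with Gaussian jitter plus
  decoys rejection-sampled to sit beyond the annotation tolerance (plus a
  3-SD jitter margin); a jitter SD ≥ tolerance/3 triggers a warning since
  recovery is then no longer guaranteed.

All draws flow from one `numpy` generator seeded by `SimConfig.seed`;
identical configurations are byte-identical. What the generators do *not*
emulate: profile-mode peak shapes, chromatography, instrument drift,
isotopic interference between co-eluting analytes, spatial autocorrelation
of real tissue, and missing-not-at-random dropout. Passing tests therefore
demonstrate correctness of the computations under the stated statistical
model, not robustness to every artifact of real acquisitions.

## Pipeline and reproducibility

The `run` orchestrator executes stages in dependency order
(simulate → annotate → flux → profile → diff → image) and writes a JSON
manifest with the configuration echo, SHA-256 checksums of every input
and output, per-stage record counts and collected warnings. Data outputs
are deterministic given (configuration, seed); the manifest's timestamps
are metadata and excluded from that contract. Stage failure exits nonzero
and retains partial outputs with the failed stage marked.

Problem sizes used by the verification scripts — 2000 null-table
replicates for false-discovery calibration, 100 simulation seeds for
effect recovery, 1000 peaks for jittered annotation, chain lengths to C30
for the isotope round-trip — were chosen as the package's own standard
check sizes; all complete in well under a minute each on a single core.

## Known limitations

* Annotation is sum-composition level only; a peak matching several
  isomeric species resolves by the documented tie-break, not by evidence.
* The fragment-rule set is minimal and illustrative of class-diagnostic
  confirmation; it is not a validated identification engine.
* The carbon-only correction model is inappropriate for deuterium tracers
  or very large K at high mass resolution.
* ROI masks are supplied as label grids; there is no annotation tooling
  or histology co-registration.
* Adjusted FDR values depend on the level q (adaptive procedure); they
  are not portable across q without recomputation.
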