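# Methods

## Acquisition model and frame bookkeeping

The pipeline targets single-plane SPIM movies of 350 frames at 5 Hz (70 s)
with optogenetic stimulation events at frames 50, 150 and 250. The SLM
illumination saturates every frame it overlaps, so those frames are deleted
before any processing. The per-event exclusion spans are stored in the
protocol, not hard-coded downstream: an event at frame *f* excludes frames
*f*+1 … *f*+2 for 100 ms ("short") pulses and *f*+1 … *f*+26 for 5000 ms
("long") pulses. These constants are exactly the ones that reproduce the
published retained lists (1–50, 77–150, 177–250, 277–350 long; 1–50, 53–150,
153–250, 253–350 short) for the standard acquisition. All serialized frame
indices are 1-based; in-memory array positions are 0-based.

## Registration

Drift correction is translation-only, integer-pixel, matching the intent of
slice-alignment plugins. Each retained frame is aligned to the mean of the
first 50 retained frames (chosen because pre-stimulation frames are
guaranteed artifact-free; the source workflow does not name its reference).
The applied shift maximizes the mean-subtracted circular cross-correlation
within a ±10 px search radius (FFT-evaluated; ties broken deterministically
in row-major scan order over candidate shifts). Out-of-frame pixels after
shifting are filled with the frame's median intensity. Subpixel refinement
and rotational/non-rigid correction are deliberately out of scope.

## Segmentation

Somata are segmented on the average projection of the registered stack by
marker-controlled watershed on the *inverted* intensity image: markers are
the extended minima (h-minima transform) at depth `tolerance` (default 18
gray levels, the documented watershed-tolerance semantics of morphological
segmentation plugins), flooded with 4-connectivity. Whether the original
workflow segmented the raw or gradient image is unstated; we segment the
inverted intensity image, which is the variant whose tolerance parameter has
the same units as the published value. Basins tile the image, so every
bright soma receives at least one ROI and a cell split across basins appears
as duplicate ROIs — oversegmentation is tolerated because near-identical
fragments are merged downstream by the r > 0.97 duplicate filter. Regions
below `min_area_px` (default 4) are dropped and labels renumbered
contiguously. Externally curated label masks can be imported to bypass
segmentation entirely.

## ΔF/F, duplicates, and classification

Per ROI and frame, the raw trace is the mean gray value over the ROI's
pixels; the baseline F0 is the mean of the first ten retained time points and
ΔF/F = ((FI − F0)/F0)·100. ROIs with F0 ≤ 0 are flagged and excluded with a
logged reason. Duplicate removal computes pairwise Pearson correlations of
the ΔF/F traces and walks ROI ids in ascending order, dropping any ROI that
correlates above 0.97 with an already-retained one (the lowest id of a
cluster survives; which member the source workflow dropped is unstated).

For each stimulation event, a 10-point window is taken: the four retained
points ending at the event frame (the event frame is always retained) and
the first six retained points after the deleted block. Whether "four time
points before" includes the event frame itself is ambiguous in the source;
we include it. Each window is correlated against model event profiles with
the sample Pearson r, and a two-tailed p from the t transform
t = r√(n−2)/√(1−r²) on n−2 = 8 degrees of freedom (tail choice and method
are our decision; the source states neither). A template qualifies only if
min r over the three events > 0.6 **and** max p < 0.001, both strict; among
qualifying templates the largest min-r wins. On 8 df the p criterion is the
binding one: p < 0.001 requires |r| > 0.8721, so the joint three-event rule
admits essentially no noise (measured < 10⁻³ over 10,000 null ROIs, and
theoretically ≈ (5·10⁻⁴)³ per template for one-sided matches).

Three model profiles are shipped although only two outcome labels exist:
*excited* (transient at stimulus onset), *inhibited_rebound* (suppression
followed by a rebound transient) and *inhibited_flat* (suppression with
recovery but no rebound); both inhibited profiles map to the label
"inhibited". The reference templates are built by averaging 50 labeled
event windows collected over five independently seeded training simulations
(10 signals per movie per class), using ground-truth cell identities and
masks; they serialize to JSON so experimentally curated profiles can replace
them. Rebound amplitude is max(post points) − mean(pre points) per event;
the habituation index is (amp₁ − amp₃)/|amp₁|, reported missing when amp₁ is
zero.

## Cohort statistics

Per-larva counts of finally-labeled ROIs are compared between groups with a
classical pooled-variance two-sample two-tailed t-test (df = n₁ + n₂ − 2),
matching the named "Student's t-test"; Welch's correction is deliberately
not applied. Identical constant groups are reported as t = 0, p = 1 with a
degeneracy flag; perfectly separated constant groups (pooled variance zero,
means different) as |t| = ∞ with the smallest representable p. A
Shapiro–Wilk p per group is reported as a descriptive normality check but
never gates the test (the source's parenthetical "(one sample t-test)" is
not a normality test; we do not guess its intent). Counts are compared raw
by default — the study plots counts per larva — with a per-total-fraction
mode behind a flag.

Type-I-error calibration uses null cohorts simulated at the per-larva count
level: both groups draw inhibited counts from the same binomial model
(n = 100 cells, fraction 0.08), which is exactly the quantity the t-test
consumes; 500 such cohorts put the empirical rejection rate at α = 0.05
within [0.03, 0.08] (measured 0.030–0.066 across seeds, mean 0.049).
Simulating 500 full 12-movie imaging cohorts would test the same statistic
at ~500× the cost without exercising any additional pipeline code.

## Synthetic data: what it emulates and what it does not

The generator renders cells as non-overlapping hard discs (radius 3 px,
brightness 100 gray) of uniform intensity on a zero background, with
additive Gaussian sensor noise (SD 3 gray), optional Poisson shot noise
(off by default), 16-bit quantization, saturating artifact frames at the
excluded-frame set, and rigid drift stepped by up to ±1 px per axis at each
stimulation event. Calcium transients are difference-of-exponentials
kernels, peak-normalized to 1 (rise 0.5 s, decay 3.0 s — slow, as
appropriate for a nuclear-localized indicator; configurable, not a claim
about any particular dataset).

Planted classes: *visual_excited* cells fire a 100 %ΔF/F transient at the
onset of every stimulation flash; *inhibited* cells are multiplicatively
suppressed toward 1 − `inhibition_depth` (default 0.8) during the
stimulation window with indicator-decay kinetics, recover with the rise
time, and fire a rebound transient at the first retained post-stimulation
frame with amplitude `rebound_amplitude`·`habituation_factor`^(k−1)
(defaults 100 %ΔF/F and 0.7) at event k; *silent* cells carry only
spontaneous events (rate 0.005 Hz, amplitude 30 %ΔF/F). Since the source
protocol quantifies neither inhibition depth nor rebound amplitude, these
defaults are free parameters of the simulation, not reproductions.

Each cell additionally receives two independent ongoing-variability
components, each normalized to an exact SD: a slow baseline drift (Gaussian
noise smoothed at a 10 s timescale, 5 %ΔF/F) modeling bleaching and slow
physiology, and a fast activity noise (0.4 s timescale, 5 %ΔF/F) modeling
small ongoing calcium fluctuations. These exist because real neurons never
produce numerically identical traces: without them, distinct cells with
identical planted responses would exceed the r > 0.97 duplicate threshold
and be merged. The chosen amplitudes keep distinct-cell trace correlations
at ≤ ~0.96 while fragments of one oversegmented cell (which share all
trace-level components) stay above 0.99, and they perturb 10-point event
windows only mildly. The 10 s drift timescale matters: much faster drift
decorrelates the pre- and post-stimulus halves of an event window (which
span ~6 s of wall time for long pulses) and degrades the weakest (third,
most habituated) rebound's correlation to the template.

What the generator does **not** model: optics (no PSF, scattering or
hologram physics), neuropil contamination, morphological diversity, bleach
trends, z-drift, or correlated network activity. Passing tests therefore
demonstrate correctness of the bookkeeping, formulas and decision rules and
recoverability under idealized imaging, not performance on real tissue —
on real data segmentation quality and neuropil contamination will dominate.

## Problem sizes and numerical choices

Default simulated movies are 128×128 px with 100 cells (8 inhibited, 25
visual-excited), the cohort is 6 vs 6 as in the modeled study, and template
training uses 5 movies per class variant — sizes chosen so a full cohort
analysis runs in tens of seconds while every count the statistics consume
remains at study scale. Watershed ties are resolved by deterministic scan
order; registration ties by row-major order over candidate shifts; the
duplicate filter visits ROIs in ascending id order; all simulations are
driven by explicit integer seeds (identical seeds give bit-identical movies,
masks and classifications). Degenerate inputs (constant images, constant
traces or windows, F0 ≤ 0, empty crops, blank registration references)
raise or flag with explicit reasons rather than propagating NaNs.

## Laminar depth profiles

Depth is normalized 0 (superficial, SO side) to 1 (deep, SAC/SPV side);
no physical scale is assumed because line profiles are typically reported
scale-free, but a slab thickness in µm is carried as metadata. Sampling
lines sit at 1/4, 1/2 and 3/4 across the slab (the "three evenly spaced
points" of manual workflows leave exact placement open; this is our
choice). Imaging-software-specific surface thresholding and µm-scale
background subtraction are replaced by a documented percentile background
subtraction (default: 10th percentile of the channel) applied before peak
detection. Peaks are detected with prominence ≥ 20% of the channel maximum
(configurable); each lamina interval is the half-prominence region around
its peak, with overlaps between adjacent intervals cut at the midpoint
between peaks. When fewer than four green peaks are found, names are
assigned superficial-to-deep in canonical order and the remainder reported
missing — adequate for well-labeled scaffolds, but wrong if a *middle*
lamina is the one that failed to label, a known limitation.

## Known limitations

- Registration is integer-pixel and translation-only; slow within-epoch
  drift smaller than 1 px is invisible to it.
- The joint three-event criterion is strict by design; cells with a
  spontaneous transient inside one event window are typically lost
  (sensitivity on synthetic data is ~0.9–1.0, not 1.0).
- The third model profile (inhibited without rebound) is a design choice to
  fill the "three model profiles / two labels" gap in the source
  description, not a reproduction of the original templates.
- With long pulses, visual onset responses are measured ~5 s after their
  peak (the peak falls in deleted frames), so excited-cell sensitivity is
  intrinsically lower in long-pulse than short-pulse movies.
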