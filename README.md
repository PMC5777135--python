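# tectastim

Analysis pipeline for optogenetic-stimulation calcium-imaging experiments in
the larval zebrafish optic tectum, plus the two-channel laminar depth-profile
analysis used to map afferent projections onto the tectal neuropil laminae.

The package is aimed at experimenters who pair sculpted-light (SLM)
optogenetic stimulation of a presynaptic population with SPIM calcium imaging
of tectal periventricular-layer (PVL) neurons expressing a nuclear calcium
indicator (H2B-GCaMP6s), and who want a tested, scriptable version of the
classic ImageJ + MATLAB workflow: artifact-frame deletion, drift correction,
watershed soma segmentation, ΔF/F extraction, and stimulus-locked response
classification, through to the per-larva group statistics.

## What it computes

**Stimulus-locked response classification.** Movies are acquired at 5 Hz for
70 s (350 frames) with stimulation events at frames 50/150/250 (100 ms
"short" or 5000 ms "long" pulses). Frames in which the SLM is active are
deleted — retaining frames 1–50, 77–150, 177–250, 277–350 (long) or 1–50,
53–150, 153–250, 253–350 (short) — then the stack is registered by
integer-pixel translation and segmented by marker-controlled watershed
(tolerance 18 gray levels) on the inverted average projection. Per ROI,

    ΔF/F = ((FI − F0) / F0) × 100,      F0 = mean of the first 10 retained frames

ROIs whose ΔF/F correlates above r = 0.97 with an already-retained ROI are
removed as duplicates. For each stimulation event a 10-point window (4
retained points up to and including the event frame, 6 after the deleted
block) is correlated against model GCaMP event profiles; an ROI is labeled
*excited* or *inhibited* only if, for some template, the minimum Pearson r
over all three events exceeds 0.6 **and** the maximum two-tailed p (t
transform, df = n − 2 = 8) stays below 0.001. Rebound amplitude (max of the
post-points minus mean of the pre-points) and a habituation index
(amp₁ − amp₃)/|amp₁| quantify release-from-inhibition firing and its decay
across trials. Per-larva counts of inhibited (or excited) neurons are
compared between ChR2⁺ and control groups with a pooled-variance two-tailed
unpaired Student's t-test (α = 0.05).

**Laminar depth profiling.** A two-channel slab (retinal axon scaffold in
green, afferent projections in red) is reduced to mean intensity vs
normalized neuropil depth by averaging three evenly spaced sampling lines.
The four retinorecipient laminae (SO, SFGS, SGC, SAC/SPV) are detected as
prominence-ranked peaks of the green profile; red peaks are then assigned to
the lamina containing them or to the gap between flanking laminae (e.g.
"between SGC and SAC/SPV").

**Synthetic data.** No public raw movies accompany this protocol, so the
`synthetic` module generates ground-truthed movies emulating it: planted
visual-excited, inhibited-with-rebound (habituating across the three trials)
and silent cells, saturating SLM artifact frames, sensor noise, and rigid
drift stepped at each stimulation event. Every downstream stage is validated
against this ground truth.

## Worked example

```python
import tectastim as ts

protocol = ts.build_protocol("long", (50, 150, 250), 350)
config = ts.SimulationConfig()                      # 100 cells, 8 inhibited
templates = ts.make_reference_templates(config, protocol, seed=99)

movie, truth = ts.generate_movie(config, protocol)
analysis = ts.analyze_movie(movie, protocol, templates)
print(analysis.count("inhibited"), analysis.count("excited"))

result = ts.run_cohort(6, 6, config, protocol, templates, seed=1234)
for s in result.summaries:
    print(s.larva_id, s.group, s.n_inhibited)
c = result.comparison
print(f"t = {c.t_statistic:.1f}, df = {c.df}, p = {c.p_value:.3g}")
```

At seed 1234 this prints per-larva inhibited counts of 7–8 for the six
ChR2⁺ larvae (8 cells planted per movie) and 0 for all six controls, ending
with

```
t = 47.0, df = 10, p = 4.58e-13
```

i.e. the prolonged-stimulation inhibition is recovered only in the group in
which it was planted, and the group difference is overwhelmingly significant
at the study's α = 0.05. The classifier stays conservative by construction:
with 10-point windows, p < 0.001 on 8 degrees of freedom requires |r| ≳
0.872 at *every* event, so noise-only ROIs essentially never qualify
(measured < 0.1% over 10,000 simulated null ROIs in the test suite).

A command-line interface mirrors the library
(`tectastim simulate | preprocess | segment | make-templates | classify |
stats | lamina`); see `tectastim --help`.

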