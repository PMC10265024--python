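# Methods

This note documents the models and numerical choices behind `callspace`:
what the synthetic generator emulates, how each analysis stage is defined,
which parameters matter, and where the design was genuinely open.

## Study design emulated by the generator

The generator reproduces the structure of a flock-formation experiment with
an open-ended vocal learner: 4-bird flocks of a single age class (young or
old adults), five 4-day recording blocks — block 1 recorded before flock
formation (the baseline repertoire), blocks 2–5 after — with 4 audio
sessions per bird per block. Social observation covers the four post-flock
blocks: 8 video sessions per flock, 11 proximity snapshots each (88 per
flock), plus continuously coded affiliative and agonistic interactions.

### Call model

A contact call is a **harmonic stack under a frequency-modulation contour**:
the fundamental follows a monotone-cubic (PCHIP) interpolation of 4 anchor
frequencies, harmonic *k* carries amplitude 1/*k* (2 harmonics by default),
a Tukey(0.2) envelope removes onset clicks, and broadband Gaussian noise is
added relative to call amplitude. This is the minimal model that carries the
quantities the pipeline measures — duration, frequency statistics, frequency
modulation — without attempting realistic psittacine timbre (a non-goal).

Calls are **individually distinctive**: each bird draws one signature base
frequency and duration; its call types (3 by default) are variants around
that signature (FM-shape changes, ±120 Hz offsets, ±8% duration jitter).
Within a flock the four signature frequencies are stratified across the
1.8–3.2 kHz base range in shuffled order, reflecting birds drawn from
separate source populations with distinct call cultures; independent draws
would allow chance signature collisions between future flockmates, which
both the real design and the parameter-recovery tests exclude.

### Vocal dynamics

Per block from block 2 on, each bird's anchor frequencies — and the call
duration, since imitation copies the whole call — move a fixed fraction
`convergence_rate` toward the mean contour of its three flockmates, and
anchors jitter with SD `drift_rate` Hz. Defaults: `convergence_rate = 0.5`
per block (adult budgerigars imitate flockmates' calls within about one
week, i.e. roughly one recording block, so a rate closing half the gap per
block is the realistic regime) and `drift_rate = 20` Hz. The generator
returns the true mean contour distance to flockmates per bird per block;
with convergence planted and drift off this decreases strictly, and it is
the ground truth the convergence statistic must recover.

**Age presets** (old relative to young): duration ×0.8, frequency ×1.15,
FM depth ×0.6, affiliative rate ×0.5, and repertoire pruning — half of the
call types are dropped once, after the baseline block (at least one type is
kept). Pruning is the mechanism by which the old cohort loses repertoire
diversity; the directions are anchored in reported age differences, while
the magnitudes are free parameters, not calibrated claims.

### Social data

Interaction counts per dyad per session are negative-binomial (mean *m*,
shape 2; variance *m* + *m*²/2), matching the count family the statistics
battery fits. Default rates are calibrated so that six flocks over eight
sessions reproduce, in expectation, the published interaction totals the
worked-example tests check (young: 316 affiliative / 202 agonistic; old:
116 / 134), i.e. per-dyad-per-session means of 316/288 etc. Proximity
snapshots mark each bird unmeasurable with probability `absence_prob`
(default 0.1; birds leave the camera's focal plane); a measurable dyad is
within 10 cm with its affinity probability (young 0.30, old 0.22 by
default — a modest decline consistent with the affiliative presets).

What the generator does **not** emulate: warble song and other non-call
vocalizations, realistic cage acoustics (reverberation, overlapping
callers), observer error in distance measurement, and temporal
autocorrelation of social behaviour within sessions. Passing tests therefore
demonstrate that the pipeline recovers planted effects under its own
assumptions, not performance on field recordings.

## Detection

Bandpass (Butterworth order 4, zero phase) → rectified envelope smoothed
with a 5 ms moving average → runs above `amplitude_threshold × max(envelope)`
(scale-free, hence gain-invariant); runs separated by less than `hold_time`
merge; runs outside `[min_duration, max_duration]` are discarded. Grid
optimization scores each candidate setting against annotations — a detection
is a true positive when it covers ≥ 50% of an annotation's duration — and
returns the F-score argmax (ties: higher recall, then lower threshold). The
signal/noise filter is a seeded random forest; any classifier meeting the
deterministic-contract would do. Human visual screening of the original
workflow is replaced by this classifier stage plus optional label overrides,
because manual inspection is not reproducible.

## Features

Audio is resampled to 19 kHz (polyphase, Kaiser β=14 anti-aliasing) and
bandpassed 0.5–8 kHz (Butterworth order 5, zero phase). The spectrogram uses
150-sample Hann windows with 50% overlap; the frequency-bin width is
19000/150 ≈ 127 Hz, and a call must span at least two windows (300 samples ≈
16 ms). Spectral statistics are moments and quantiles of the time-averaged
magnitude spectrum restricted to the band; entropies are Shannon entropies
normalized by log bin-count (so bounded in [0, 1]); overall entropy is the
product of spectral and temporal entropy; flatness is the geometric/
arithmetic mean ratio of the power spectrum. The dominant-frequency track is
the per-frame argmax bin; the modulation index is the track's total
variation divided by its range (1 for a monotone sweep, larger for
oscillating contours, defined as 1 when the range is zero).

The feature vector has 17 entries. The dominant-frequency range
(max − min) is also reported as a convenience column but excluded from the
scaled 17 because it is an exact linear combination of two other features.
Scaling is z-scoring with the population-SD convention; zero-variance
columns are an error naming the column.

## Trait space, areas, overlaps

All calls enter **one joint t-SNE** (perplexity 30, 1000 iterations, PCA
initialization, Barnes–Hut, fixed seed ⇒ bit-reproducible); comparisons
between spaces are meaningless across separately fitted embeddings, and
every acoustic space therefore lives on one shared 200×200 grid spanning the
joint embedding padded by 3 bandwidths.

Per subset (≥ 5 points), the density is a Gaussian KDE with Silverman's rule
on the subset's own points, renormalized on the grid. When a subset is
narrower than the grid can resolve (bandwidth under half a cell — e.g. a
fully converged bird late in the experiment), the kernel is evaluated with a
diagonal bandwidth floored at half a cell so that probability mass always
lands on the lattice; areas below one cell are not resolvable by
construction. The HDR at level L (default 0.95, configurable) is the
smallest cell set accumulating mass L in density order; its area is the
diversity measure. Verified calibrations: the 95% HDR area of a standard
bivariate normal matches π·χ²₂(0.95) within a few percent at n = 50 000, HDR
mass is within two maximal cell masses of L, areas scale quadratically under
coordinate dilation, and areas/overlaps agree with a finer-grid numerical
integration within 2%.

The directional overlap O(A→B) = P_A(hdr A ∩ hdr B)/P_A(hdr A) was an open
design point (the descriptive requirement was a density-weighted proportion
with a single pairwise mean): this definition makes self-overlap exactly 1,
weights overlap by where A's mass actually sits, and is asymmetric in the
direction the nesting oracle predicts (a tight space overlaps a wide
concentric one more than conversely). The reported statistic is the
arithmetic mean of the two directions.

Vocal metrics follow directly: diversity change is area minus block-1 area
(block 1 ≡ 0); plasticity is overlap with the own block-1 space, stored as
similarity (block 1 ≡ 1); convergence is overlap with one pooled KDE of the
three flockmates' calls of the same block (a single combined space, not a
mean of three pairwise overlaps). Convergence is computed for blocks 1–5
with block 1 flagged as pre-exposure; recovery tests fit the block-slope
over all five blocks, where the planted signal is strongest.

## Social networks

Proximity edges are proportions of *valid* snapshots (distance measured for
both birds) with the dyad ≤ 10 cm, threshold inclusive; proportions handle
unequal observation counts across dyads. Interaction edges are undirected
counts with actor/receiver collapsed; an optional period filter restricts to
the first (blocks 1–2) or second (blocks 3–4) half of the observation
window. Density binarizes edges (> 0) over the 6 possible dyads; strength
sums incident weights. Both equal brute-force enumeration on random
matrices, and strength satisfies the handshake identity exactly.

## Statistical battery

Vocal responses are modelled per bird per block with fixed effects age
(young indicator), block (continuous), and their interaction, which is
dropped and the model refit when non-significant at α = 0.05 (an α ≥ 1
disables the interaction outright). Overlap- and area-based responses are
baseline-relative, so only blocks 2–5 enter those models. Families:
negative binomial (log) for counts, Gaussian for area change, beta (logit)
for proportions; network density is binomial over 6 trials per flock and
strength is negative binomial (counts) or gamma (inverse link; proximity).
Beta responses at the boundary are squeezed by (y(n−1)+0.5)/n before
fitting.

Estimation is a contract, not a library mandate; the committed estimators
are: a linear mixed model with crossed individual and flock intercepts for
Gaussian responses; maximum-likelihood beta regression with a cluster-robust
sandwich; and, for negative-binomial responses, GEE with an exchangeable
working correlation and the Mancl–DeRouen bias-reduced covariance, with the
NB shape profiled from a pooled ML fit. Because age varies *between flocks*,
all sandwiches cluster at the flock level — clustering at the individual
level ignores flock-level correlation and inflates type-I error several-fold
— and Wald statistics are referenced against t distributions with
cluster-count-based degrees of freedom (G−1 for sandwich fits, G−2 for the
mixed model), since the normal reference is anti-conservative at a dozen
clusters. Under these choices the simulated type-I error of the age test
sits inside [0.03, 0.08] for all three families, and planted effects are
recovered without material bias. Reported statistic types follow the
convention t for Gaussian, z otherwise. Complete separation (e.g. all
flocks at density 6/6) is flagged `degenerate` on the fit rather than
raised.

## Pipeline and reproducibility

Stages run simulate → detect → features → space → metrics → network →
models under one YAML config; every stochastic stage derives its seed as
`(master_seed·1000003 + crc32(stage)) mod 2³¹`, so a rerun with the same
config is bit-identical through the embedding. Each run writes an immutable
`manifest.json` (versions, seeds, parameters, input hashes). Selection
tables use the Raven tab-separated dialect with 6-decimal times; tabular
outputs are CSV with headers.

## Problem sizes

The test-suite and acceptance computations use deliberately compact study
sizes chosen to exercise every code path at comfortable statistical power:
replicate flocks of 4 birds × 5 blocks × 25–30 calls, embeddings of a few
hundred calls (perplexity 20–25), 100–200-cell grids for replicate KDEs and
the full 200-cell grid for calibration against closed forms, 20 replicate
experiments for parameter recovery, and 200–250 simulated datasets per
family for test calibration. Default pipeline sizes (2 flocks × 4 birds ×
5 blocks, ~100 calls/bird/block) are larger and complete in minutes.

## Known limitations

- t-SNE geometry is not metric: areas and overlaps are comparable within a
  joint embedding, not across embeddings or seeds; seed-to-seed overlap
  statistics correlate strongly in rank but are not numerically identical.
- Silverman bandwidths oversmooth widely separated multimodal subsets (a
  repertoire with very distinct call types); overlaps between such subsets
  are conservative in the sense of being inflated toward each other's
  modes.
- The beta/NB sandwich inference is asymptotic in the number of flocks; at
  fewer than ~8 flocks the t-referenced tests become conservative.
- The generator's age presets fix directions with free magnitudes; contrasts
  on synthetic data are sign checks, not effect-size claims.
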