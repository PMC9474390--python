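# Methods

This note documents the models and procedures implemented in `orgephys`, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical choices that matter. Units follow one
convention everywhere: times in seconds (float64), coordinates in µm,
amplitudes in µV, channel indices 0-based, intervals end-exclusive.

## Synthetic world

The generator emulates the activity regime of cerebral-organoid slices on a
planar HD-MEA (26,400 electrodes, 17.5 µm pitch, 10–20 kHz sampling):

* **Spiking.** Each unit fires as a homogeneous Poisson process at
  `unit_rate` (default 0.38 Hz). Population bursts arrive as a Poisson
  process at `burst_rate` (0.01 Hz) with fixed length `burst_duration`
  (4.05 s). Inside a burst every unit's rate is multiplied by a raised-cosine
  envelope (0.5 s on/offset ramps) reaching `burst_gain` (20×), with the
  burst excess modulated sinusoidally at `burst_osc_freq` (14.33 Hz, depth
  0.8). Inhomogeneous rates are realized by thinning. The burst model is
  phenomenological: no pacemaker or recurrent mechanism is claimed, only the
  MUA statistics the detector assumes. Overlapping bursts superpose by
  envelope maximum, so a Poisson overlap appears as one long burst — which is
  also what the detector (correctly) reports.
* **Synapses.** A directed edge (i→j, delay d, probability p) adds, for each
  source spike, a target spike at t+d with probability p, in one pass (no
  cascades). Delays must be ≥ 1 ms, because the connectivity stage excludes
  sub-millisecond CCG peaks as putative duplicate signals; a generator world
  violating that would be unrecoverable by construction.
* **Footprints.** An EF assigns electrode k on the axonal path a spike
  template delayed by cumdist(k)/velocity and scaled by
  exp(−cumdist(k)/decay_const); off-path electrodes carry Gaussian noise.
  Templates are biphasic (1.5 ms, somatic), triphasic (axonal) or wide
  monophasic. Optional Gaussian latency jitter models trough-time variability
  of weak axonal signals; 20 µs is the cohort-benchmark value.
* **LFP.** Burst-gated channel-group signals: 1/f^χ background (default
  χ = 2) synthesized by FFT shaping, plus a sinusoid at the burst oscillation
  frequency inside burst windows.
* **Determinism.** All draws flow from one root seed through named
  substreams (per unit, per edge, per channel group), so enlarging a
  simulation never perturbs what was already generated; identical truths and
  seed give byte-identical outputs.

What the generator does **not** emulate: raw full-array voltage traces,
electrode-level noise correlations, biophysical cable properties, bursting
rate heterogeneity across units, spike-sorting errors other than the two QC
rules, and electrode drift beyond per-day amplitude scaling in the tracking
tests. A green recovery test therefore establishes that the chain measures
what it claims on data satisfying its assumptions — not that it is robust to
sorting artifacts absent from this world.

## Unit QC and footprints

A unit is removed when the fraction of its inter-spike intervals below 1 ms
exceeds 5% of its spike count. Duplicate removal considers unit pairs whose
EF peak channels lie within 100 µm; spikes of the smaller-trough unit within
0.5 ms of a larger-trough spike are dropped (ties break toward the lower unit
id). Both filters are idempotent and only delete rows. Spike-triggered
averaging uses a 2 ms pre / 3 ms post window (covering the 3 ms clustering
snippet with margin) and requires 30 fully-contained spikes; the "too little
activity" exclusion defaults to 50 spikes per recording.

The peak channel maximizes the *negative-going* trough amplitude
(max of −min, floored at 0), not |min|: a channel with a purely positive
deflection has no trough and can never be a peak channel.

## Burst detection

MUA is binned at 0.1 s. The vector is normalized by the maximum of its
Gaussian-smoothed version (SD 0.3 s). Burst peaks are local maxima of the
smoothed vector exceeding mean + 2·SD; onset and offset are the nearest
crossings of the mean level; bursts closer than one bin merge and bursts
shorter than 0.5 s are discarded. Normalization makes the rule scale-free:
uniformly rescaling the MUA changes nothing.

One choice deserves emphasis: the mean/SD *statistics* and the onset/offset
*crossings* are evaluated on the raw normalized vector, while peak *finding*
runs on the smoothed vector. Smoothing exists to stabilize peak detection; if
it also supplied the SD, the threshold would sit only ~2 shrunken-SDs above
the mean and constant-rate Poisson input would generate tens of false bursts
per 10 minutes, and if it supplied the crossings, every burst would be
widened by roughly twice the kernel SD (a ~20% duration bias at 4-s bursts).
With the raw vector both effects vanish: on constant-rate input the detector
returns zero bursts, and 4.05-s generative bursts are measured at ~4.1 s.

## Burst-LFP spectra

LFP is resampled to 1 kHz; Welch spectra (1 s Hann segments, 50% overlap) are
computed per burst window and per channel group of 7–8 adjacent electrodes
(groups are the generator's native channel unit). Each spectrum is decomposed
over 2–100 Hz as log₁₀P(f) = offset − exponent·log₁₀f + Σ Gaussians: a robust
two-pass straight-line fit of the aperiodic part (refit on the
lowest-residual 75% to resist peaks), then iterative extraction of up to 6
Gaussian peaks (width bounded 1–12 Hz), each accepted only if its fitted
height ≥ 0.3 log₁₀-power units above the aperiodic component, then an
aperiodic refit on the peak-subtracted spectrum. Fit failure degrades to the
aperiodic-only model with a warning. Peak centers pooled across bursts and
groups are summarized by the mode of a Gaussian KDE (1 Hz bandwidth, 0.05 Hz
grid). Note that short burst windows give noisy Welch estimates, and isolated
noise excursions can clear the 0.3 threshold in single-burst spectra; the
pooled mode is what is stable.

## Axonal velocity

EFs below 20 kHz are upsampled. Per channel the trough time is referenced to
the peak channel's; channels below the noise floor or with negative latency
are masked. The floor is 5 × 1.4826 × MAD of the channel's pre-trough
baseline; because that baseline is short (~30 samples), per-channel MADs are
floored at the across-channel median MAD — otherwise occasional underestimated
floors admit noise troughs that derail path extraction. Trough times default
to sample resolution; 3-point parabolic interpolation is available
(`velocity_subsample_interp`).

The flow graph has a directed edge i→j iff latency(i) < latency(j) and the
electrodes are ≤ 60 µm apart; strict ordering makes it acyclic. "Clusters"
are the weakly connected components of the subgraph induced on the electrodes
reachable from the peak (the natural reading for a sparse latency DAG); for
each cluster the minimum-cumulative-length (Dijkstra) path from the peak to
the cluster's Euclidean-farthest electrode is the traced segment. Exact
length ties break toward the path visiting more electrodes, so a straight
chain is traced electrode-by-electrode and contributes the densest possible
regression. Velocity is the OLS slope of cumulative distance (m) on latency
(s), pooled over segments; this direction makes the slope m/s directly, and
r² is direction-independent. Estimates need ≥ 3 pooled electrodes and count
toward cohort statistics only when r² > 0.8.

**Known limitation.** Because segments are traced by the geometrically
shortest path, an axon that curves back within the 60 µm edge reach creates
shortcut edges and its travel distance is under-measured: on gently curved
random-walk paths the recovered velocity runs ~10% low. The recovery
benchmark therefore uses straight paths (the generator's `random_axon_path`
also refuses to double back within ~3 pitches). Sample-resolution troughs at
20 kHz add ±25 µs quantization, a few-percent effect over typical 100–200 µm
traces.

## Waveform clustering

Peak-channel waveforms at ≥ 20 kHz are high-pass filtered (150 Hz, 2nd-order
zero-phase Butterworth), cut to 61 points from 1 ms before to 2 ms after the
filtered trough (61 points at 20 kHz is 3.05 ms; the point count is taken as
authoritative, and "AP peak" is read as the trough, consistent with trough
normalization), and normalized so the minimum is −1. Flat (zero-trough)
waveforms are excluded.

Clustering consumes the fuzzy nearest-neighbor graph built by the UMAP
embedding step (15 neighbors, min_dist 0.1, seeded) — not the 2-D
coordinates — partitioned by Louvain at a given resolution; Q is the
standard (resolution-1) weighted modularity of that partition on that same
graph. The resolution sweep rebuilds the graph once and reruns Louvain
`n_iter` times (default 20) with seeds root+iteration.

A property worth knowing: modularity maximization on a k-NN graph of a single
homogeneous cloud of points happily subdivides it once the resolution exceeds
~1, because UMAP's locally-normalized affinities give even noise blobs
internal structure. Well-separated waveform families are therefore recovered
*exactly* at coarse resolutions (≤ 0.5 in the tests) and split into pure
sub-clusters — never mixed — at the headline resolution 1.5. Cluster counts at
resolution 1.5 should be read with that in mind.

## Connectivity

**CCG.** Counts of target spikes relative to source spikes in 1 ms bins over
±50 ms (bin k centered on lag k ms). The baseline is the CCG convolved with a
Gaussian kernel (SD 10 ms, truncated ±3 SD, edge-renormalized; the peak bin
itself is included — no hollow kernel). The peak is the maximum count among
bins with 1 ms ≤ |lag| ≤ 5 ms; p = P(X ≥ peak | λ = baseline at that bin) by
the exact Poisson survival function, significant at α = 0.001 with no
correction across the window's bins (a single α, as published; the
error-control test verifies the realized false-positive rate still sits below
2α thanks to Poisson discreteness at sparse-firing baselines). If the overall
monosynaptic-window maximum falls in the < 1 ms bin the pair is excluded —
sub-millisecond peaks are duplicate-signal artifacts, not synapses. A zero
baseline under a nonzero peak is floored at 1e−10 and flagged. Each unordered
pair is tested once; the peak's lag sign sets the edge direction.

**Transfer entropy.** Spike trains are binned and binarized (any spike ⇒ 1).
TE(source→target) is the plug-in estimate
Σ p(jₜ, j_hist, i_hist) log₂[p(jₜ|j_hist,i_hist)/p(jₜ|j_hist)] with target
history 1 bin and source history 4 bins taken at delay 1 bin, i.e. lags
delay…delay+3 — at bin 35 ms the source window is 35–140 ms. The estimator
enumerates joint patterns exactly but touches only time points within reach
of a spike (all others share the all-zero pattern), so cost scales with spike
count, not recording length. Significance: 50 surrogates jitter each source
spike independently by a uniform integer offset in {−3…3} (7-bin width;
collisions collapse), the target stays fixed; z = (TE −
mean_surr)/SD_surr > Φ⁻¹(1−α) declares an edge; zero surrogate SD is
degenerate and never significant. The time-scale ladder is 8 log-spaced bin
sizes {1, 1.6, 3.5, 7.4, 16, 35, 74, 160} ms, reconstructed from the three
published anchors (range 1–160 ms, scale 2 = 1.6 ms, scale 6 = 35 ms).

**Error control, honestly.** The CCG test is conservative in practice: at
sparse-firing baselines the discrete Poisson tail realizes well below its
nominal level, and the measured false-positive fraction on an independent
50-unit, 1-h network is ~0.0008 at α = 0.001. The TE surrogate z-test is
*anti-conservative* by construction: under independence the plug-in TE is
approximately a scaled χ² with modest degrees of freedom (few occupied
history patterns at sparse firing), so its null is right-skewed, and
comparing a z-score against the Gaussian 0.999 quantile realizes a
false-positive fraction of ~0.007 — about 7α — on the same independent
network. This is a property of the published recipe (50 surrogates, Gaussian
z threshold), not of the estimator: the identical inflation appears when the
surrogate distribution is simulated directly. It is consistent with the
TE route detecting several-fold more connections than the CCG route on the
same data. Users wanting calibrated TE error rates should replace the z
threshold with a surrogate-rank (permutation) p-value at correspondingly
larger surrogate counts; the package keeps the published rule and the test
suite records its realized rate.

**Graph summaries.** Density is the fraction of ordered unit pairs with a
significant edge; Q is the Louvain modularity of the symmetrized binary
significant-edge graph (undefined, reported as missing, when edgeless).

## Tracking

The published tracking analysis concatenates sessions and re-sorts them; that
is out of scope here, and this module substitutes the standard template-
matching surrogate: footprints of consecutive days (identical electrode
configuration required) are matched by the Hungarian assignment maximizing
total cosine similarity of flattened waveforms, accepting matches ≥ 0.85.
Cosine similarity makes matching gain-invariant; chains of consecutive
matches define units tracked across spans, so tracked counts are
non-increasing with span by construction. Published tracked-unit counts are
therefore only qualitatively comparable.

## Numerical notes

* All randomness descends from one root seed via named `SeedSequence`
  substreams; every public stochastic function takes a seed.
* CCG bin edges are half-open [k−½, k+½) ms; spike-time binarization is
  floor(t/bin) with end-exclusive range.
* The Poisson tail uses `P(X ≥ n)` exactly (survival function at n−1), no
  continuity correction.
* Degenerate inputs: empty spike tables are legal everywhere except the CCG
  of an empty train (undefined, skipped); identical snippets collapse to one
  cluster; a latency map with fewer than two included electrodes yields no
  velocity estimate.
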