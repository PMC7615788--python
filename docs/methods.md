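# Methods

This note documents the models, rules and numerical choices behind
`netphen`, in the order data flows through the pipeline.

## MEA spike detection

Raw extracellular voltage (channels × samples, µV, 10 kHz nominal) is
band-pass filtered at 100–3500 Hz with a 2nd-order Butterworth applied
forward and backward (`sosfiltfilt`), so spike timestamps are not biased
by filter group delay. Spikes are detected on both polarities at
|v| > k·σ with k = 4.5. The noise scale σ defaults to the spike-robust
estimator median(|v|)/0.6745 rather than the raw SD, because the raw SD is
inflated by the spikes themselves at high firing rates; a `raw` mode is
provided for compatibility with software that uses the plain SD. Each
contiguous supra-threshold excursion is timestamped at its absolute
extremum, and a 1 ms dead time suppresses double counting of the two
lobes of a biphasic waveform. A channel with zero signal range yields an
empty train with a warning, not an error. The detector is invariant to
positive rescaling of the trace (threshold and signal scale together).

## Burst and network-burst rules

Per channel, bursts are maximal runs of spikes with consecutive
inter-spike intervals ≤ 50 ms; runs separated by less than the minimal
inter-burst interval of 100 ms are merged; runs with fewer than 5 spikes
are discarded; the burst span is first-to-last member spike. The 50 ms
within-burst interval is a common max-interval default and is exposed as
a parameter (only the 5-spike minimum and the 100 ms inter-burst interval
are fixed by the protocol this mirrors).

A network burst is computed by an exact interval-overlap sweep: the
number of channels with an open burst is tracked through every burst
start/end, and maximal epochs where the count reaches
⌈participation × n_channels⌉ (participation = 0.5) are emitted, with
epochs closer than 100 ms merged. The participation denominator is all
channels in the well. Bursting channels are those above 0.4 burst/s
(strictly above). Note one subtlety: the epoch *count* is not guaranteed
monotone in the participation threshold — an epoch whose channel count
dips mid-way can split into two at a higher threshold — but total
qualifying time is monotone, and that is the invariant the tests assert.

Well metrics: MFR = unweighted mean of channel spike frequencies
(count/duration); network-burst rate per minute; mean network-burst
duration; inter-network-burst interval measured end→next-start (mean),
reported as missing when fewer than two network bursts exist; burst spike
rate = mean over channel bursts of n_spikes/duration. Because a burst
spans first-to-last spike (slightly shorter than the generating epoch),
the measured within-burst rate sits a few percent above the generator's
nominal rate; group contrasts are unaffected.

## Synthetic MEA wells and the phenotype presets

A well is simulated as: (i) network-burst epochs drawn as an
exponential-gap renewal process at `nb_rate`, with Gaussian durations and
a 0.11 s minimum inter-epoch gap — just above the 100 ms merge rule, so
every planted epoch is individually resolvable by the detection side;
(ii) within each epoch, a random ⌈participation × n_channels⌉ subset of
channels firing Poisson at `within_burst_rate`; (iii) independent
single-channel bursts at `channel_burst_rate`; (iv) Poisson background
throughout. Default 12 channels per well (a typical 24-well MEA layout),
600 s recordings.

The presets encode the study signature — equal global activity, different
temporal organization:

| parameter            | control | mutant_like |
|----------------------|---------|-------------|
| nb_rate              | 0.05 /s | 0.10 /s     |
| nb_duration_mean     | 1.0 s   | 0.6 s       |
| within_burst_rate    | 60 Hz   | 50 Hz       |
| channel_burst_rate   | 0.02 /s | 0.04 /s     |
| background_rate      | 0.5 Hz  | 0.5 Hz      |

Expected per-channel rate = background + nb_rate·dur·participation·rate
+ channel_burst_rate·dur·rate = 3.95 Hz in both groups; empirically the
two presets agree to within 0.02 ± 0.02 Hz over 1000 wells (residual
truncation asymmetries are ≤ 0.002 Hz analytically). The magnitudes
(≈3–6 network bursts/min, MFR ≈ 4 Hz) are plausible for mature
hiPSC-derived networks; the source study reports its values graphically
only, so the presets are calibrated to its qualitative signature, not to
printed numbers.

Raw-waveform rendering inserts a fixed 1.5 ms biphasic template (negative
trough = spike amplitude, scaled exactly) into Gaussian noise. This is
adequate for threshold-crossing detection, not for spike sorting. No
quantitative raw-noise statistics were available to emulate; the defaults
(3 µV noise, 30 µV spikes) were chosen for detector testability.

## Patch clamp

Synaptic events are inward deflections below a running-median baseline
(200 ms window, reflection-padded; computed on a decimated copy for long
traces). The detection threshold is max(min_amplitude, 3× robust noise
SD of the residual); the amplitude floor has *no hidden default* — the
original interactive analysis did not report one, so callers must supply
it. A 0.3 ms boxcar smooths the residual for crossing detection and
amplitude measurement (raw-trough amplitudes carry a positive noise
bias), and sub-millisecond re-crossings are merged into one event.

Event bursts follow the run reading of the protocol: maximal runs with
consecutive inter-onset gaps ≤ 50 ms, qualifying when they hold ≥ 3
events and a maximum amplitude strictly above 100 pA. The generator
plants such epochs by construction (gap draws in 5–45 ms, one amplitude
forced above threshold), so classifier round trips are exact.

Intrinsic properties: Vrmp = mean pre-stimulus potential; R_in = ΔV/ΔI
from the −10 mV step (mV/nA → MΩ); membrane τ by mono-exponential fit of
the step transient; adaptation ratio = (t₉−t₈)/(t₃−t₂) with 1-based AP
numbering, missing when fewer than 9 APs fire; AHP time from the
repolarization's crossing of the per-AP threshold potential (located by
a 10 mV/ms dV/dt criterion) to the AHP minimum; AP half-time from the
peak to 50 % of the peak-to-AHP amplitude. AHP metrics are averaged over
APs with a resolvable minimum before the next AP. QC fails at series
resistance > 25 MΩ or membrane/series ratio < 10; the source text prints
the ratio as "10:0", which is arithmetically degenerate and implemented
as the 10:1 reading (flagged in the docstring, never silently
normalized in reports).

## Calcium imaging

Order of operations is fixed: bleach-correct, then F₀, then ΔF/F.
Bleaching is fitted as a·exp(−t/τ)+c on baseline frames (those at or
below a 10 s running median — this excludes transients from the fit) and
removed by dividing the trace by the fit normalized to its initial
value. The multiplicative correction preserves ΔF/F under any positive
rescaling of the raw trace and recovers pre-bleach transient amplitudes
exactly for the generative model. Degenerate fits (constant trace,
< 1 % fitted decay, non-convergence) fall back to no correction with
τ = ∞, which also makes double correction idempotent. F₀ is the lower
10th percentile of the corrected trace (the percentile is a parameter;
the protocol does not define F₀).

Transient onsets are upward crossings of k·(time-local robust noise SD)
(k = 3, floored at 0.01 ΔF/F for noiseless traces) of the trace
referenced to a 15 s running median, with a 0.5 s refractory period and
hysteresis (re-arm below a third of threshold). The local noise estimate
matters because additive acquisition noise is amplified by the bleach
division toward the end of a recording. Synchrony is a coincidence
statistic: frames where ≥ ⌈participation × n_ROIs⌉ ROIs have an onset
within ±1 frame, consecutive qualifying frames collapsed into one event,
reported per minute. The original in-house synchrony statistic is not
reproducible from its description; this coincidence rate is a declared
stand-in, with the 0.5 participation default mirroring the MEA
network-burst rule. With fewer than two ROIs synchrony is undefined.

The fluorescence generator draws shared network events with a 5 s
minimum gap (≈5 transient decay constants) — closer events stack on an
undecayed tail and are unresolvable by any level-crossing detector, so
the generator emulates resolvable network events by design.

## Morphology

SWC files are validated structurally (single root, no orphans, no
cycles, all nodes reachable; offending node ids are reported). Axon-typed
nodes are excluded from all dendritic metrics. Morphometrics: soma area
as the equivalent circle of the root radius; primary dendrites = dendritic
children of the root; nodes = dendritic branch points; ends = dendritic
leaves; total length = summed parent–child segment lengths; mean length =
total per primary dendrite; covered area = 2-D convex hull (x–y) of
dendritic sample points.

Sholl shells are concentric spheres at 20 µm intervals around the soma
centroid (a 2-D circle mode is provided; whether the original software
measured 2-D or 3-D shells is not stated). Segments are split exactly at
shell boundaries by solving |a + s·d| = r per segment, so shell lengths
sum to the total dendritic length to machine precision. Intersections
count geometric boundary crossings; a node lying exactly on a boundary
carries one crossing per child on the opposite side from its parent — so
a dendrite passing through a boundary at a node counts once, while a tip
touching a boundary counts zero. Branch nodes are binned by radius.

The tree generator distributes an exact length budget recursively
(branching with configurable probability, piecewise-straight geometry
with per-step angular jitter), which guarantees the total path length
matches the target and makes length-conservation tests sharp.

## Statistics and reporting

Group comparisons mirror the source conventions: Shapiro–Wilk normality
per group (reported, not acted on by default), unpaired Student's *t* for
two groups, one-way ANOVA with all-pairs Bonferroni-corrected *t* post
hocs for more, two-way ANOVA (type II, independent samples) for
genotype × timepoint designs, two-sample Kolmogorov–Smirnov for
per-event cumulative distributions, and star bands at 0.05/0.01/0.001.
No fallback is prescribed when normality fails, so a rank-based
(Mann–Whitney) alternative sits behind an explicit flag and the
parametric test remains the default. Groups with n < 3 are flagged
unreliable rather than dropped. Pharmacology contrasts support paired
(matched wells, mismatches are an error listing the offending wells) and
unpaired designs. The experimental unit is the well for MEA and the cell
for patch/morphology; no mixed-effects nesting is attempted.

The pipeline expands one study seed into independent per-well
substreams (`SeedSequence.spawn`), so adding a well never perturbs
another's draws; every artifact is stamped with the config hash and
seed, and report figures are byte-deterministic (fixed SVG hash salt, no
embedded dates).

## Problem sizes and verification scope

The shipped tests exercise: burst grouping against an independent
cluster-merge oracle on 1000 random trains (≤ 50 spikes); the
sEPSC burst rule against exhaustive run enumeration on 1000 random event
sets (≤ 15 events); spike detection on 120 s of raw 12-channel voltage
at 8× noise amplitude (recall ≥ 0.95, false positives ≤ 0.5 Hz/channel);
planted network-burst recovery over 20 seeds of 600 s wells; Sholl
length conservation on 100 random trees; type-I calibration of the
two-group path over 10,000 simulated nulls at n = 10/group; and the full
control-vs-mutant study contrast at 10 wells/group over 20 replicates.
These sizes keep the default suite under a minute while leaving the
statistical assertions well-powered.

## Known limitations

- Generators are statistical, not biophysical: no conductance-based
  dynamics, no electrode-field model, no astrocyte effects; passing
  round-trip tests shows the analysis recovers the planted statistical
  structure, not that it would be unbiased on every real recording.
- The MFR non-significance property is a true null tested at α = 0.05,
  so any single replicate has ≈5 % probability of flagging it; joint
  criteria over many replicates inherit that binomial variability.
- Spike detection does not sort units or reject artifacts beyond
  thresholding; event detection does not fit per-event kinetics or use
  template deconvolution; calcium analysis does not infer spikes from
  transients; no liquid-junction-potential correction is applied.
- Closely spaced calcium events (< 5 s at the default decay) and
  synaptic events overlapping within ~1 ms are not resolvable by design.
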