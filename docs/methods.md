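# Methods

This note documents the models and conventions implemented in `placeseq`,
the design choices made where the published conventions leave the procedure
open, what the synthetic generator does and does not emulate, and the known
limitations.

## Coordinate and phase conventions

Track position is an angle in degrees, in [0, 360), increasing in the
running direction; linear quantities convert via the track circumference
(default 100π ≈ 314.16 cm for a 1-m-diameter track). All circular distances
are shortest-arc unless stated signed. Theta phase is 0° at the filtered
waveform peak and 180° at the trough; this choice is arbitrary (the
literature uses both peak- and trough-zero conventions) and only affects
intercepts, never precession correlations or sequence statistics.

## Behavior

Speed is estimated by central differences on the unwrapped angle followed by
a 5-sample boxcar (~167 ms at 29.97 Hz). The smoothing suppresses tracker
jitter that would otherwise toggle samples across the 5 cm/s locomotion
gate; the estimator itself is a convention, not a published fact. Laps are
completed 360° passes of the unwrapped angle in the running direction, which
makes the count invariant to the angular origin.

## Rate maps and place fields

90 bins of 4°; spike counts divided by occupancy, both restricted to samples
at ≥ 5 cm/s; smoothing by a wrap-around Gaussian with σ = 8° (2 bins),
truncated at 4σ and renormalized. Bins with zero gated occupancy take a raw
rate of 0 before smoothing — on a circular track with tens of laps such bins
are essentially absent, and this choice keeps NaNs out of the circular
kernel (the alternative, occupancy-weighted smoothing, changes nothing in
practice here).

Day-average maps pool spikes and occupancy across the four run sessions
rather than averaging per-session maps; pooling equals the rate definition
applied to the whole day and weights sessions by time actually spent moving.
Units must reach a 1 Hz day-map peak to be analyzed further; units with
whole-day mean rates above 5 Hz are flagged putative interneurons and
excluded from place-cell analyses (but never deleted from the session).

Place-field detection z-scores the 90 smoothed rates with the unweighted
bin mean and SD (the occupancy-weighted variant is a defensible alternative;
unweighted was fixed as the convention), seeds fields at z ≥ 2, grows them
circularly until z < 0.5, merges touching regions, and drops fields below
18° or 1 Hz peak.

## Circular–linear regression

All trajectory and precession fits maximize the mean resultant length of the
residual angles (phase − slope·x) over a two-stage slope grid (241-point
coarse grid over the bounds, then a 41-point fine grid around the coarse
optimum). The same deterministic procedure is used for observed and shuffled
fits, which keeps the shuffle null exchangeable. Slope bounds: ±1,080
deg/field for precession (three theta cycles), ±3,000 deg/s for theta
sequences, ±5,000 deg/s for replay — generous covers of reported values, all
configurable. Goodness of fit is r² = 1 − V(resid)/V(total) with V the
circular variance and residuals taken as shortest arcs to the line; this
reduces to the ordinary coefficient of determination in the small-angle
limit and is clipped into [0, 1]. A zero-variance set of angles is a perfect
fit by convention. The precession correlation r is the standard
circular–linear correlation (Pearson correlations with the sine and cosine
components combined); its p-value uses the χ²(2) approximation of n·r².

## Bayesian decoding

Independent-Poisson likelihood over units with day-averaged tuning curves,
flat spatial prior, log-domain evaluation with tuning floored at 0.01 Hz
inside the logarithm. Windows with zero spikes are decoded (the posterior is
then ∝ exp(−τΣλ), peaking where the summed tuning is lowest) but flagged;
replay classification drops them before fitting, because their center of
mass marks a fixed property of the tuning model rather than a represented
position. Theta-sequence analysis instead uses the published contiguity
rule: the longest run of windows unbroken by two consecutive spikeless
windows. The decoding gate (median error of speed-gated 500 ms / 100 ms
windows below 20°) must pass before sequence or replay stages run.

Tuning curves are estimated from the same day that is decoded, as in the
source procedure; no cross-validation is applied, which inflates accuracy
slightly relative to held-out decoding.

## Theta sequences

The cycle-cutting phase is the minimum of an 18-bin (20°) histogram of
place-cell spike phases, ties resolved toward the smallest phase; 20° is
coarse enough to be stable at realistic spike counts and fine enough to
localize the trough. The shuffle test rotates every window's posterior
circularly by an independent uniform number of bins and refits; since
rotating a posterior by k bins rotates its circular center of mass by
exactly k·4°, the implementation applies the offsets to the COM angles
directly — an identity, not an approximation. x-span is |slope|·t-span
(the regression line's own extent, an absolute arc length) and t-span is
measured center-to-center across the windows used; both are conventions
where the published definitions are ambiguous.

On decoded data the shuffle null is conservative in one direction and
anticonservative in another: because adjacent 40 ms windows overlap by
75%, neighboring COMs share spikes and the observed r² distribution is
inflated relative to independently rotated windows. The full criterion
stack (shuffle test plus the 60%-mass and 20°-proximity rules) is what
controls the false-positive rate; on structureless cycles it passes ~1–2%
of events (see `null_calibration`), well under the nominal 5%.

## Replay

Candidate detection builds a 1 ms population-rate histogram (the finest
natural bin at millisecond spike resolution) smoothed with σ = 10 ms; the
mean and SD are computed per rest session, tracking slow drifts. Events are
bounded where the rate crosses the mean, merged across gaps ≤ 40 ms, trimmed
inward to the first/last spike, and filtered at 50–2,000 ms and ≥ 5
participating cells ("participated" = fired ≥ 1 spike within the trimmed
bounds; the cell count uses the units active on the track, not all recorded
units). No speed gate applies during rest (the rat sits off the track).
Classification fits the COM of spike-containing 20 ms windows; replay
requires r² ≥ 0.5, a maximum adjacent-window jump ≤ 25% of the track, and
occurrence in rest sessions 2–5. Path distance is the shortest arc between
the first and last window COMs, and slopes are reported as absolute values
so forward and reverse events pool.

## LFP analyses

Time–frequency power uses a complex Morlet wavelet with ~7 cycles of support
at every frequency (bandwidth set so the ±3σ envelope holds 7 periods),
1 Hz steps from 2 to 250 Hz, computed on peri-onset segments padded by
500 ms to absorb edge effects. Rows are rescaled to an L1 wavelet
normalization so a pure tone peaks in its own frequency row; without this
the default L2 scaling biases peak-frequency estimates low by ~2 Hz in the
ripple band. The event-average map is z-scored within each frequency row
over the peri-event window; per-event summaries (peak ripple frequency,
slow-gamma z) standardize with statistics pooled over the day's peri-event
segments, since a single event is too short to z-score against itself.
Peak-frequency ties resolve to the lower frequency. The peri-event extent
(±500 ms) is a parameterized default. Ripple detection filters 150–250 Hz
(4th-order zero-phase Butterworth in second-order sections — the
transfer-function form is numerically unstable at these narrow normalized
bands), takes the Hilbert envelope, smooths with σ = 8 ms, z-scores, and
keeps excursions with z ≥ 3; a ripple counts toward an event when the
intervals overlap.

## The synthetic generator

`placeseq.synthetic` scripts a full day — rest1, run1, …, run4, rest5 — with
defaults matching the recording conditions the pipeline assumes: 10-minute
epochs, 29.97 Hz tracking, 2 kHz LFP, a 1-m-diameter track, ~34 cm/s
running, 8 Hz theta, 60 units with evenly spaced ~36° Gaussian fields and
15 Hz peak rates. Spikes are drawn by thinning a homogeneous Poisson process
at the intensity ceiling, which is exact for the scripted intensity. Tests
and the acceptance script shrink epoch durations and event counts; those are
problem-size choices, stated per study, not different conditions.

Run epochs support two intensity models. The *precession* model multiplies
Gaussian place tuning by a von Mises factor whose preferred phase advances
linearly with normalized field position (default one full cycle per field,
κ = 2). The *sweep* model instead evaluates the tuning at a represented
position that runs ahead of the rat at a scripted speed within each theta
cycle, resetting at phase 0 — this produces theta sequences of known slope
(and phase precession as a by-product). A mild within-cycle envelope
(κ = 0.5, minimum at the reset phase) anchors the minimum-spike cutting
phase to the sweep reset. Two properties of the estimator are visible on
this model and worth knowing: fitted slopes shrink by roughly 10% relative
to the scripted sweep because 40 ms windows average a third of a cycle with
spike times pulled toward the envelope peak, and stronger envelopes shrink
them further. Both are estimator attenuation, not generator error; scripted
compressions 300–900 deg/s are recovered monotonically (rank correlation
1.0 on per-condition medians).

Rest epochs emit baseline Poisson firing (0.2 Hz) plus scripted replay
events: each unit fires Poisson(3) spikes with 3 ms jitter as the scripted
trajectory crosses its field center, and the LFP gains Hann-enveloped
ripple bursts (80 ms every 120 ms) during the event. Baseline firing is
silenced within 50 ms of each scripted event, emulating the network
quiescence that flanks real population bursts; without it, stray baseline
spikes trapped inside the mean-crossing bounds create single-spike edge
windows whose COM breaks the jump rule. The "wt" preset scripts fast
dynamics (600 deg/s sweeps and replay, ~200 ms events, 200 Hz ripples); the
"fxs" preset scripts slowed dynamics (350/330 deg/s, ~420 ms events, 175 Hz
ripples) with unchanged spikes per event, so in-event rates fall and
interspike intervals stretch — the direction of every contrast the pipeline
is meant to resolve.

What the generator does **not** emulate: trial-to-trial rate-map
instability and remapping, interneurons, theta frequency and amplitude
fluctuations, sharp-wave deflections accompanying ripples, non-Poisson
spike-train structure (bursting, refractoriness), reward-site field
accumulation, and behavioral pauses. Passing tests therefore demonstrate
that the pipeline recovers the structures it targets at realistic signal
levels — not that it is robust to every pathology of real recordings.

## Numerical and degenerate-input choices

Zero-variance rate maps yield no place fields and a null spatial
correlation with a warning; a 0/0 rate overlap is null with a warning;
silent maps have undefined spatial information (null with warning). Cells
below the 50-spike precession minimum are returned as excluded records, not
errors. Decoding rejects all-zero tuning models. Candidate events with no
interior spikes are dropped. All randomness in analysis (shuffle tests) and
generation flows from explicit seeds through `numpy.random.default_rng` /
`SeedSequence`, so identical seeds and configuration reproduce day reports
bit for bit.

## Known limitations

Group-level inference is limited to Wilcoxon rank-sum contrasts between two
day reports; hierarchical (mixed-model) inference across animals and
sessions is out of scope. The pipeline analyzes one day at a time; cross-day
stability is limited to the session pairs within a day. The t-span of theta
sequences is insensitive to generator presets (cycle length is fixed by
theta frequency), so slow-preset contrasts express themselves in slope and
x-span. Only unidirectional running on a circular track is supported; there
is no directional splitting or 2-D rate-map support.
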