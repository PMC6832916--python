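# Methods

This note documents the models, defaults and numerical choices behind
`lans_ecg`, and what the synthetic validation does and does not establish.

## Torso grid

Electrodes are numbered row-major, six per row, seven rows per side, front
side first (ids 1–42) then back (43–84).  Front measurement squares span
electrode-row pairs (1,2), (2,3), (4,5), (5,6), (6,7): the physical square
row between electrode rows 3 and 4 is absent because the chest is not
planar there.  The front's 5 × 5 square grid is nevertheless indexed as
logically contiguous, so 8-neighborhoods behave uniformly on both sides;
this is required for the fine stage around a mid-chest ROI to use the
squares directly above and below it.

Channel 5 is the principal diagonal (top-left → bottom-right electrode
pair) and channel 6 the counter diagonal; these are fixed by the reporting
convention of the protocol.  Channels 1–4 are assigned as 1 = top
horizontal, 2 = bottom horizontal, 3 = left vertical, 4 = right vertical.
This assignment is a package convention (the four non-diagonal indices are
not pinned by the protocol's published tables); all selection logic is
orientation-aware and does not depend on it.

For the coarse stage, two squares are "adjacent" when they share an
electrode.  On the front side this is slightly weaker than logical
8-adjacency (square rows 2 and 3 are logical neighbors across the skipped
physical row but share no electrodes).  The sharing-based reading is used
because the constraint exists to keep coarse squares electrically disjoint.
The documented maximum of A = 20 coarse squares is carried as a protocol
constant; the validator checks pairwise non-adjacency only, not whether a
given A admits a placement.

Electrode coordinates place the two sides on parallel planes separated by
a configurable torso depth (default 20 cm), with back columns mirrored so
front and back squares stack geometrically.  These coordinates only feed
the simulator.

## Simulator

A single current dipole of fixed position and orientation sits inside an
infinite homogeneous volume conductor.  The potential at electrode r is
k · m(t) · (axis · (r − origin)) / ‖r − origin‖³, with m(t) a dimensionless
beat waveform: one Gaussian per P/Q/R/S/T component (defaults: amplitudes
0.15, −0.12, 1.0, −0.20, 0.35 relative to R; centers −200, −35, 0, +35,
+240 ms; widths 25, 10, 12, 12, 45 ms — ordinary adult resting morphology).
Because the dipole direction never changes over the cardiac cycle, each
lead's trace is m(t) times a constant signed gain, which makes the true
per-lead QRS amplitude analytic: |gain| × the template's QRS span.  This is
deliberately simpler than a rotating heart vector; it reproduces the two
effects the placement search must detect — amplitude decay with distance
and dependence on alignment with the electrical axis — while keeping
ground truth exact.  The emitted clean projection is zero-mean (an
AC-coupled front end cannot pass the DC component of a beat train); this
matters because the SNR estimator charges everything below ~0.4 Hz to the
noise estimate.

`plant_source` places the dipole under the center of a chosen square at a
depth of 6 cm and solves the moment scale so the chosen channel's true QRS
amplitude is exactly 1 mV.  With the default noise model the planted lead's
ground-truth SNR is ≈ 22 dB, and neighboring squares fall in the low teens;
this matches the amplitude/SNR regime the protocol's thresholds (21 dB,
1 mV) are written for.  Noise defaults: baseline sinusoids 12 µV @ 0.25 Hz
and 8 µV @ 0.12 Hz, white noise 8 µV RMS, powerline 6 µV @ 50 Hz, each with
independent random phase per channel.  The record decomposes exactly (to
float precision) into clean + noise, which the tests rely on.

Studies draw per-subject variability as a multiplicative log-normal dipole
strength (σ of log = 0.35, giving an across-subject amplitude CV ≈ 0.36,
inside the 0.40–0.75 range the protocol's CV metric is meant to resolve)
and a uniform positional offset of at most 1 cm per planar axis.  Records
are seeded per (subject, square) through spawned seed sequences, so results
are invariant to simulation order.  Default acquisition: 200 Hz, 60 s,
75 bpm with 3 % R-R jitter.

What the simulator does *not* emulate: a moving cardiac vector (hence no
realistic 12-lead morphology), torso inhomogeneity, electrode-skin
impedance, motion artifacts, or pathological rhythms.  Passing recovery
tests therefore show that the pipeline correctly inverts the
location/orientation geometry under realistic noise — not that it would
reproduce any particular subject population's numbers.

## Preprocessing

Zero-phase (forward-backward) order-4 Butterworth band-pass, 0.5–45 Hz by
default: the band keeps all QRS energy (< ~40 Hz at 200 Hz sampling) while
rejecting drift and attenuating mains interference.  Then an 8-level
`bior3.5` wavelet decomposition with symmetric extension; the level-8
approximation (0 – fs/512 ≈ 0.39 Hz at 200 Hz) is zeroed, removing baseline
wander, and detail coefficients are soft-thresholded with the universal
threshold σ√(2 ln n), σ = MAD(level-1 details)/0.6745.  Signals shorter
than the 8-level support are decomposed at the maximum feasible level.
The removed component is retained per channel: `raw = clean + removed`
holds to float precision and feeds the SNR estimate
10 log₁₀(mean(clean²) / mean((raw − clean)²)).

## QRS detection

Slope-threshold detection: 5-point central derivative, rectification,
150 ms moving average; a candidate peak of this feature must exceed 0.5 ×
its running 2 s maximum *and* 2.5 × its global median.  The second (noise
floor) gate is needed because the running-maximum threshold is
self-normalizing — on a signal-free channel it would fire everywhere; the
median gate exploits the high crest factor of real QRS slope bursts.
Accepted candidates are refined to the local trace maximum within ±75 ms
and a 200 ms refractory keeps the taller of any conflicting pair.  Channel
polarity is normalized first (a lead whose orientation opposes the
electrical axis has an inverted QRS): the trace is flipped when its extreme
deviation from the median is negative.

Q and S are the nearest local minima scanned backwards/forwards from R
within 100 ms (physiological QRS ≤ 120 ms); if a window contains no
interior minimum the window edge is used and flagged.  Per-beat amplitude
is v(R) − min(v(Q), v(S)).  Channels with fewer than 3 beats in a record
are flagged low-quality and excluded from aggregation.

All detector parameters are configurable; the defaults above are package
choices, since the protocol's published description of this stage is a
block diagram without numbers.

## Aggregation and selection

Per record and channel: SNR estimate, mean/SD/CV of beat amplitudes.
Across subjects, per lead: mean ± SD of per-subject SNR and of per-subject
mean QRS amplitude; CV = across-subject SD / mean (sample SD, n−1 — the
standard choice at n = 19).  CVs are stored and reported as fractions,
matching how the protocol's result tables print them (their "%"-labelled
column actually lists fractions, and consistency with the printed values
wins).  Reports round SNR and amplitudes to 2 decimals and CV to 3.

ROI selection ranks squares by the median SNR pooled over their six
channels and all subjects (SNR is the primary metric; medians are used
because the protocol judges "best distribution" from box plots), ties
broken by median QRS amplitude, then lowest index.  Best-channel selection
applies the same ranking across the six channel indices over the nine
fine-stage squares.

Candidate voting runs by default over the best channel's lead in each
fine-stage square (`per_best_channel`, the procedure the protocol's worked
example actually executed); a `global` mode voting over all 54 fine-stage
leads is available.  Leads measurable in fewer than half the study's
subjects are excluded from the pool — with 2 of 19 usable subjects a lead's
across-subject CV is an artifact, and on synthetic data the barely
detectable leads are exactly the ones that produce such rows.  Every
ranking has a full deterministic tie-break chain (SNR, then QRS amplitude,
then square/channel index), and the winner of a vote tie is the lead with
the better SNR rank, so identical inputs always give identical results.

Two printed-value caveats are handled explicitly in the tests: of the nine
published fine-stage CV values only one (SD 0.16 / mean 0.37 → 0.432)
equals SD/mean of its printed columns at three decimals — the others were
evidently computed from unrounded inputs — so only that row is asserted;
and the 60 Hz attenuation of the band-pass is asserted against the filter's
own frequency response evaluated in steady state, away from the
forward-backward edge transients.

## Validation sizes

The parameter-recovery experiment runs the full study configuration
(19 subjects, 17 squares, 60 s records, default noise) across 20 seeded
replicates and requires ROI and best-channel recovery in ≥ 90 % and
winning-pair recovery in ≥ 85 % of runs.  The noise-degradation property
(recovery rate non-increasing in white-noise level) runs at reduced size —
5 subjects, 20 s records, 8 seeds per level at 8, 80 and 400 µV white
noise — chosen so the three levels straddle the regime where detection
collapses while the check stays cheap.

## Known limitations

- The dipole is static; morphology across leads differs only by a scale
  factor, so metrics that depend on waveform *shape* differences between
  orientations are not exercised.
- The counter-diagonal channel of the planted square has exactly zero gain
  by symmetry; real recordings never null a lead perfectly.  Downstream
  code treats it as any other signal-free channel (flagged low-quality).
- SNR estimation attributes everything the preprocessing removes to noise;
  if the band-pass clipped genuine signal energy the estimate would be
  biased low.  With the default template the bias is < 1 dB (asserted).
- A_max = 20 is not derived from the adjacency structure; the package
  validates non-adjacency of whatever coarse set it is given.
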