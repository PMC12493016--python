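# Methods

`soclas` re-implements, as a tested library, the signal-processing and
statistical machinery of a closed-loop acoustic stimulation (CLAS)
sleep-EEG protocol: an online slow-oscillation (SO) detector and stimulus
scheduler that can be replayed deterministically over any recording,
offline SO and spindle detectors, power-spectral and stimulus-locked
analyses, and running nonparametric statistics with FDR control.  Because
the human polysomnography such pipelines are normally run on is not
publicly deposited, the package ships a synthetic polysomnography
generator with exact ground truth; every stage of the pipeline is
exercised against it.

## The online controller

The controller monitors one prefrontal channel (Fpz by default).  Two
causally filtered streams are derived at 200 Hz: an SO stream (0.25–4 Hz)
and a broadband stream (0.25–45 Hz).  Causality is a hard requirement —
the controller's output up to time *t* must depend only on samples up to
*t*, verified by a truncation-equivalence test — so zero-phase filtering
is forbidden here.

*Filter design.*  A single causal Butterworth band-pass of order ≥ 2 with
a 0.25-Hz high-pass edge rings for several seconds after each SO and can
displace the apparent trough by ~2 s.  The streams therefore use a
composite design: an order-1 high-pass at the low edge plus an order-4
low-pass at the high edge.  This keeps the SO trough essentially in place
(≲ 10 ms displacement for an isolated event) while still attenuating a
10-Hz tone by > 30 dB in the SO stream.

*Detection.*  A stimulation pair is triggered when (1) the SO stream
crosses an adaptive negativity threshold and (2) the delta/theta power
ratio of the trailing 5 s of the broadband stream (delta 0.5–4 Hz over
theta 4–8 Hz, Welch estimate, refreshed every 0.5 s) is above the
individual NREM gate (default 23.6, the population mean of the visually
selected per-subject values).  The threshold starts at −80 μV and is
updated every 0.5 s to `min(−80, mean trough amplitude of the preceding
5 s)`; troughs are the minima of all sub-threshold excursions of the SO
stream, tracked irrespective of gating.  The `min` form means the
criterion tracks deepening SOs but is never laxer than the starting
value — the trigger-threshold trace is asserted ≤ −80 μV in tests.

*Scheduling.*  On a detection, burst 1 is scheduled at the detection time
plus the individualized delay (default 500 ms; per subject it is the mean
SO trough→positive-peak interval of an adaptation night, computed by
`individual_delay`), and burst 2 follows at a fixed 1075 ms.  The bursts
themselves are 50 ms of pink 1/f noise with 5-ms ramps.  A refractory
pause of at least 2.5 s follows burst 2 before the detector re-arms, and
re-arming additionally requires the signal to rise back above threshold
(a refractory timer expiring mid-crossing does not fire).  Stimulation is
gated at the epoch level: it becomes available only after 4 min of
continuous artefact-free N3 for the first deep-sleep bout (2 min for
later bouts), stays available through N2/N3, is cut by any epoch lighter
than N2 or flagged artefactual (after which stability must re-accrue),
and is restricted to the first 4 h of the recording.

*Timing accuracy.*  The threshold crossing necessarily leads the trough
by an amount set by SO steepness.  For ~1-Hz SOs (negative half-waves of
0.5–0.7 s) the median offset between burst 1 and trough + delay is below
50 ms at high SNR; for the much slower SOs the offline detector is tuned
to (see below), the lead grows to ~110 ms.  The timing test therefore
uses a steep-SO session; on real mixed-frequency sleep the offset lies
between these figures.

*Gate selection.*  The per-subject delta/theta gate is normally chosen by
eye from two histograms (ratio per 30-s epoch, NREM versus Wake∪REM).
`select_dt_threshold` automates this as the smallest unit-width bin edge
*t* maximizing `P(ratio ≥ t | NREM) − P(ratio ≥ t | Wake∪REM)` — the
point where Wake/REM epochs have dropped off while NREM epochs remain
abundant.  Identical class distributions trigger a degeneracy warning.

## Offline SO detection

The signal is band-pass filtered 0.5–3.5 Hz with a zero-phase order-1
Butterworth (applied forward–backward, so effective order 2).  The gentle
order matters: SO fundamentals sit at the 0.5-Hz band edge, and steeper
zero-phase filters shorten the detected negative half-waves by up to
~0.3 s, pushing genuine events below the duration bound.

Candidate events are negative half-waves — the interval from a
negative-going zero-crossing to the next positive-going one — with
durations of 0.75–2 s, followed by the positive half-wave up to the next
negative-going crossing (unconstrained in duration).  Detection is
restricted to artefact-free N2/N3 epochs; candidates touching other
epochs are discarded whole.  Per channel, two relative thresholds are
computed over all candidates: 1.25× the mean trough amplitude and 1.25×
the mean trough-to-peak amplitude; an SO is a candidate surpassing both.
Thresholds can be computed on one session and frozen for another
(`compute_so_thresholds` + the `thresholds` argument / the
`--thresholds-from` CLI flag), mirroring the practice of deriving both
conditions' thresholds from a single reference session.

Note a structural property of relative thresholds: in a *homogeneous*
population (all troughs equal) 1.25× the mean exceeds every trough and
nothing is detected.  Detection requires amplitude heterogeneity, and the
weaker part of any injected population is rejected by design.  Recovery
on synthetic data is therefore quantified two ways: recall over
*threshold-eligible* injections (the clean injected waveform, filtered as
the detector filters it, surpasses the session thresholds with a 10 %
margin) must be ≥ 0.9 at high SNR, and recall over all injections must be
monotone in SNR.

Derived per-event properties: length (negative + positive half-wave
durations), peak-to-peak amplitude, and the down-to-up-state slope
(peak-to-peak amplitude over the trough→peak interval).  Summaries report
count, density per 30 s of artefact-free NREM (density × NREM epochs =
count, exactly), mean amplitudes/durations and the positive/negative
half-wave length ratio.

## Spindle detection

Individual slow (9–12 Hz) and fast (12–16 Hz) spindle peak frequencies
are read off the artefact-free-NREM power spectrum (the same 4096-point
Hanning grid as all spectra, so "± frequency resolution" means 0.12 Hz at
500 Hz).  Peaks on a range boundary or of low prominence are reported
with warnings rather than rejected.

Detection runs on the 35-Hz low-passed, 100-Hz downsampled signal.  Per
type, a linear-phase FIR band-pass of 3-Hz width centred on the peak
frequency (≈ 1-Hz transition band) is applied; the envelope is the RMS
over a 0.2-s sliding window (step one sample) smoothed by a 0.2-s moving
average.  Thresholds are 1.5 SD (detection) and 2.5 SD (peak criterion)
of the band-passed signal restricted to artefact-free NREM.  Segments of
0.5–3 s above the 1.5-SD threshold containing at least one sample above
2.5 SD become spindles; neighbouring detections closer than 0.5 s merge
when their combined supra-threshold time stays below 3 s (otherwise both
are kept separate).  Slow and fast detection are independent; an interval
crossing both bands may legitimately appear in both lists.

Two consequences of this construction are worth stating.  First, because
both thresholds are standard deviations of the signal itself, the
detected event set is exactly invariant to global amplitude scaling and
to DC offsets (tested).  Second, the RMS windowing and the FIR smear the
envelope, so the supra-threshold duration of an event is not the duration
of the underlying burst: how much of a short burst survives the 0.5-s
minimum depends on where the 1.5-SD threshold sits relative to the burst
envelope.  In realistic NREM — where ongoing sigma activity sets the SD —
a 0.3-s burst is rejected and a 1-s spindle is detected at roughly its
half-maximum width; tests construct exactly this situation.

## Spectra and stimulus-locked analyses

Power spectra are Welch averages of Hanning-windowed 4096-point
periodograms with 50 % overlap, computed within contiguous artefact-free
N2/N3 stretches only (runs shorter than one window are skipped; no
stretch at all is an error), density-normalized so a unit-variance white
signal integrates to ≈ 1.  Band powers integrate the PSD over half-open
bands — SO 0.5–1.5, delta 1.5–4, SWA 0.5–4, theta 4–9, slow spindle
9.5–12.5, fast spindle 12.5–15.5 Hz — and are log10-transformed (zero
power is an error rather than −∞).  Half-open bands make SWA exactly the
sum of the SO and delta bands.

Stimulus-locked traces low-pass the EEG with a linear-phase FIR whose
−3-dB point is tuned by bisection to 32.0 Hz, downsample to 100 Hz, snap
each first-burst trigger to the 100-Hz grid and cut half-open [−1, 3) s
windows (exactly 400 samples).  Windows touching the recording edge, an
artefact epoch or a stage outside N2/N3 are excluded and counted.
Baseline normalization subtracts each epoch's mean over [−0.99, −0.01] s;
it is idempotent and makes the traces invariant to recording-level
offsets.  Spindle-RMS time courses apply the spindle band-pass → RMS →
smoothing chain before epoching and are baseline-normalized by default.
Per-session averaging always precedes grand averaging (`grand_average`
weighs sessions, not epochs), matching per-subject-first statistics.

## Statistics

`wilcoxon_signed_rank` drops zero differences, assigns mid-ranks to tied
absolute differences, and uses the exact sign-assignment null (computed
by polynomial convolution over the 2^n patterns, n ≤ 15) with a
tie-corrected normal approximation beyond.  The exact p equals a literal
enumeration oracle over random cases in the tests.  All-zero differences
return p = 1 with a degeneracy flag.

`running_wilcoxon` applies the paired test at every point of a shared
time grid (n ≥ 5 subjects) and reports both the raw p < 0.05 mask and the
Benjamini–Hochberg mask at q = 0.05 — the dual uncorrected/corrected
display used in the CLAS literature.  Tie-free columns share one cached
exact null distribution, which makes 500-replicate null simulations cheap;
the simulated pointwise level sits at the nominal 5 %.  BH is the
standard step-up rule with monotone adjusted p-values (verified against
statsmodels), applied per comparison family (one channel's time course).

`sleep_architecture` computes TST (N1+N2+N3+REM minutes), WASO (Wake
after the first sleep epoch), efficiency (100·TST / time in bed),
per-stage minutes and % of TST, and REM minutes in each night half, split
at the midpoint of time in bed (the split point is otherwise undefined).

## The synthetic generator

`generate_session` produces (recording, hypnogram, ground truth) triples,
fully determined by a seed; random streams are split per event family so
adding spindles never perturbs SO placement.  The background is pink
(1/f) noise with stage-dependent SD (18–20 μV in N2/N3, 15 μV otherwise)
plus stage-specific colouring: extra 0.5–2-Hz delta in N2/N3 (8/12 μV)
and extra 4–8-Hz theta in Wake/REM.  Most N3 delta power comes from the
injected SOs themselves, as in real slow-wave activity — inflating the
background delta instead fragments SO half-waves with spurious
zero-crossings and defeats any zero-crossing detector.

SOs are biphasic half-sine waveforms (negative then positive lobe)
injected in N2/N3 at Poisson rates (5/epoch in N3, 1.5/epoch in N2) with
troughs drawn from −150 to −80 μV and half-wave durations of 1.0–1.4 s;
starts are placed without overlap (rejection sampling).  The long
default durations are deliberate: the offline detector bounds the
*negative half-wave* at 0.75–2 s, and the 0.5-Hz band edge shrinks
half-waves by ~0.2 s, so events must be generated slow enough to remain
detectable.  Spindles are Hann-enveloped sinusoids (slow ~10.3–11.3 Hz,
fast ~13.0–14.0 Hz, 15–30 μV, 0.6–1.5 s), half of them coupled with onset
at a host SO's positive peak.  Evoked responses are damped biphasic
(K-complex-like) templates added at trigger + latency.

Default scale is a full 8-h night at 500 Hz; tests and the acceptance
script use 10–30-min sessions with explicit stage plans, which exercise
the identical code paths at desk scale.  What the generator does *not*
emulate — asymmetric SO shapes, non-stationary background, arousal
microstructure, topographic gradients (events are injected identically on
all channels) — bounds what passing tests show about real data: they
validate the machinery (timing, thresholds, bounds, invariances), not
clinical detector performance.

## Degenerate inputs and numerical conventions

Sample indexing is 0-based; event intervals are half-open [start, end);
times are seconds from recording start.  EDF round trips are exact to one
16-bit quantization step of each channel's range (the native HDF5
container is lossless).  An all-zero delta/theta window is defined as a
neutral ratio of 1 with a warning.  Empty event lists summarize to count
0 with NaN means.  Unknown hypnogram tokens and config keys are hard
errors naming the offending line/key.
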