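# Methods

This note records the models behind `cinegate`, the parameter choices, and
what the synthetic studies do and do not demonstrate.

## Physiology model

The heart is modelled as its R-peak point process only: downstream logic
(gating delays, DSA frame timing, phase sorting) consumes trigger times,
not waveform morphology, so no P/QRS/T synthesis is attempted. RR
intervals are `mean_rr + N(0, rr_jitter_sd)` with independent draws per
beat; the jitter standard deviation is restricted to below `mean_rr/3`
(plus a clip at 5% of `mean_rr`) so intervals stay positive. Defaults for
the rat: `mean_rr` 143–150 ms, jitter ≈ 8 ms — enough irregularity to
exercise EMA prediction and phase binning without pathological beats.

Respiration is a ventilator schedule: breaths of period `60/rate` with a
piecewise-linear volume surrogate (linear rise over the inspiratory
fraction, linear fall over expiration). Phase 0 is breath onset, which
coincides with the end-expiratory baseline. A breath hold `(start, end)`
suppresses cycle starts in the interval and resumes at `end`; during the
hold the phase function is frozen at the end-expiratory value 0.0 and the
waveform sits at baseline. Holds default to the 5–10 s band typical for a
DSA run.

The trigger comparator fires on rising threshold crossings of a uniformly
sampled waveform (default 1 kHz) and suppresses events within a refractory
period. Threshold and refractory are configuration, not constants, since
hardware conditioning settings vary per animal.

## Gating sequencers

*Prospective*: per beat, the candidate exposure is
`R_k + phase_frac · RR_k` using the beat's own RR interval; it fires only
inside the respiratory phase window (default (0.85, 1.0), late/end
expiration). After an exposure the sequencer is inhibited for
`max(rotation_settle, min_frame_interval)`. One exposure per angle gives a
strictly regular angular set. The cine variant repeats the whole rotation
per phase delay, which is why its simulated scan time is an order of
magnitude above FPG's.

*Retrospective*: the pacer is free-running at `frame_rate ≤ 10` frames/s
(the detector readout ceiling; 100 ms period at the maximum). Angles grow
linearly within each continuous rotation. Phase sorting assigns each
exposure the most recent R peak at or before it — the only monotone
reading of "previous peak closest to the sampling time" — with phase
fraction `(t − t_prevR)/RR` and half-open bins `[k/N, (k+1)/N)`, clamped
to N−1; exposures before the first or after the last R peak stay
unassigned. With a rotation period incommensurate with the (jittered) RR,
per-bin angle sets are irregular.

*Fast prospective gating*: the next RR is predicted by an exponential
moving average, initialized at the first observed interval, default
α = 0.3 (neither weight nor initialization is dictated by the hardware
design; α = 0.3 adapts within a few beats while smoothing jitter, and both
are configurable). Phases are scheduled in order at
`R_k + frac · p_k`; a phase whose exposure would violate the detector dead
time is deferred to the earliest later beat whose delay clears it (greedy,
order-preserving — exposures remain time-monotone by construction). The
rotation trigger is emitted only after all phases at the current angle.

## DSA and functional analysis

The event sequence: the run uses the first breath hold of the respiration
trace; frames are exposed at successive R peaks inside it. The injector
command is placed at the last pre-contrast frame — the bolus is exactly
zero at the injection instant, so that frame is uncontaminated and the
first post-injection beat already samples the rising bolus. The default
protocol is 40 frames with 6 pre-contrast at one frame per heartbeat,
which at RR = 150 ms yields 34 post-injection heartbeats inside a 7 s
hold. A hold too short for the frame budget raises an error stating the
required duration.

Mask subtraction defaults to linear (`frame − mask`); log mode
(`ln mask − ln frame`) is provided because quantitative analysis on
transmission projections strictly requires line-integral contrast. The
synthetic scene adds enhancement linearly, so the linear mode is exact
there.

The gamma-variate bolus is the standard first-pass form in peak-normalized
parameterization, `A·((t−t0)/(αβ))^α · exp(α − (t−t0)/β)`: `A` is the peak
height and the maximum sits at `t0 + αβ`, which conditions the fit far
better than the textbook `A·(t−t0)^α e^{−(t−t0)/β}`. Initialization: onset
at the sample before the curve first exceeds 10% of its peak, α = 3, β
from the peak position; samples after the curve falls back below 10% of
peak are excluded as a recirculation guard. Fitting is
`scipy.optimize.curve_fit` with bounds.

Patlak: `x = ∫₀^t Cb dτ / Cb(t)` (trapezoidal on the sampled grid, curves
zero before injection), `y = C/Cb`, ordinary least squares. The default
fit window is all samples after the bolus peak of Cb with Cb > 0 — the
quasi-equilibrium phase; which heartbeats enter the regression is
configurable because protocols differ. On noiseless model-generated data
the estimator is exact up to trapezoidal integration error for any Cb
shape.

Perfusion index = peak tissue enhancement / trapezoidal aortic AUC, which
is invariant under common rescaling. Note that for a tissue obeying the
Patlak model the index is determined by (rbv, K, bolus shape); the
dedicated generator `synthesize_perfusion_tac` instead scales a tissue
bolus so the index equals a requested value by construction, which is how
study-magnitude indices (0.0555 cortex, 0.0544 medulla) are round-tripped.

## Synthetic kidney scene

Aorta, cortical annulus and medullary core on a 64² grid over static
anatomy. The aortic bolus is a gamma variate with amplitude 100 a.u.,
α = 3, β = 0.55 s, onset 0.25 s post injection — a fast rat arterial first
pass peaking ≈ 1.9 s after injection, leaving most of the 34-beat window
in the post-peak Patlak regime. Its cumulative integral is computed in
closed form via the regularized incomplete gamma function, so tissue
curves `C = rbv·Cb + K·∫Cb` are model-exact, not numerically integrated.
Generating magnitudes default to the cortex/medulla values above. The
scene omits real-data features — recirculation, partial-volume mixing at
ROI borders, detector noise and scatter, motion during the hold — so
recovery tests demonstrate correctness of the estimators, not robustness
to those effects; the noisy recovery suite (5% multiplicative noise on
both TACs, 100 seeds) probes statistical stability only.

## Phantom tomography

Parallel-beam 2D geometry replaces the cone-beam bench deliberately: the
gating questions (phase consistency, angular regularity) are
geometry-independent, and 2D admits analytic oracles — chord-length
projections of disks, exact ground-truth images at any phase. The beating
phantom modulates the blood-pool radius as
`r_d·(1 − amp·(1−cos 2πc)/2)` (end diastole at phase 0, end systole at
0.5) and the lung ellipse with the respiratory phase.

The projector samples the image with linear interpolation at half-pixel
steps along each ray and sums with length weighting. FBP ramp-filters each
view (optionally Hann-apodized) in the Fourier domain with zero padding,
backprojects with linear detector interpolation, and weights each view by
half the angular gap between its circular neighbours — the natural
quadrature for irregular angle sets; duplicate angles from repeated
rotations are averaged first. Full-circle data is halved. Advanced
irregular-angle remedies (bilateral filtering, PSF deconvolution,
total-variation reconstruction) are intentionally out of scope.

Fixed tolerances: the static-disk interior RMSE bound (0.08 on a
unit-attenuation disk, 128² grid, 360 views) was frozen from a dense-view
oracle measurement of ≈ 0.052, dominated by edge Gibbs ringing, with
headroom for grid parity effects. The chamber-radius estimator thresholds
pixels inside the myocardial outer radius at the blood/wall midpoint and
reports the equivalent-area circle radius; it carries a small positive
bias from reconstruction blur, which cancels in correlation and
monotonicity checks.

## Study sizes and determinism

Simulated studies use 30–360 angles, 128² grids, 5 rotations at 10
frames/s, and 100-seed noise ensembles — sizes chosen so each experiment
has comfortable statistics while a full run of the suite completes in well
under a minute of CPU apiece. All randomness flows from one top-level seed
through named CRC32-derived substreams (`experiment.substream`), so any
stage can be re-run independently; experiment recipes write sha256
manifests and identical configs reproduce byte-identical outputs.

## Known limitations

No hardware timing (FPGA loop rates, stepper dynamics, injector
mechanics); no X-ray physics (spectra, scatter, beam hardening, dose); no
absolute concentration calibration — all enhancements are arbitrary units;
respiratory assignment emits phase fractions only, not
inspiration/expiration labels; the prospective sequencer models the
respiratory gate as a phase window rather than a hardware delay-counter
coincidence, which is equivalent for the simulated trains.
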