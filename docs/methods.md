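# Methods

## The model

`gammaecho` simulates a pyramidal–interneuron gamma (PING) network as a
model of early visual cortex, and provides the analysis stack used to
characterize its "gamma echo": the damped gamma-band component of the
temporal response function (TRF) relating a broadband input train to
the population signal.

The network contains `n_e` regular-spiking excitatory cells (E) and
`n_i` fast-spiking interneurons (I), 400/100 by default.  Each cell is
an Izhikevich unit

    v' = 0.04 v² + 5 v + 140 − u + I + I_syn
    u' = a (b v − u)

with reset `v → c`, `u → u + d` when `v` crosses +30 mV.  E cells use
(a, b, c, d) = (0.02, 0.2, −65, 8); I cells (0.1, 0.2, −65, 2).  Each
cell carries a synaptic gate

    s' = α F(v) (1 − s) − β s,      F(v) = 1 / (1 + e^(−v/2))

(AMPA on E cells: α = 12 ms⁻¹, β = 0.5 ms⁻¹; GABA on I cells: α = 12,
β = 0.1).  The synaptic current into receiver k is

    I_syn(k) = Σᵢ C[k,i] s_AMPA(i) (v_AMPA − v_k)
             + Σⱼ C[k,j] s_GABA(j) (v_GABA − v_k)

with v_AMPA = 0 mV and v_GABA = −70 mV on E targets, −75 mV on I
targets.  Connectivity is dense within the allowed blocks with base
strengths c_ii = 0.004, c_ie = 0.006 (I→E), c_ei = 0.003 (E→I),
c_ee = 0; every realized weight is the base strength times an
independent Uniform[0, 1] draw, and self-connections are removed.
Trials differ only in this weight jitter (and in the stimulus noise,
where the stimulus is stochastic).

The population signal — the model's local-field/MEG proxy — is the
per-step average of the E-cell membrane potentials, with spike
excursions capped at +30 mV for recording.

### Integration

Forward Euler at Δt = 1 ms (configurable).  All right-hand sides,
including the gate drive F(v), are evaluated at the incoming state of
the step (standard simultaneous Euler); the threshold test uses the
updated potential and the reset is applied afterwards.  Gates are
clipped to [0, 1], which at Δt = 1 ms makes a spike effectively set the
sender's gate to 1 (the Euler increment α·F·(1−s)·Δt exceeds 1 near
threshold); the gate then decays at β.  We verified on a two-cell E–I
motif that this loop agrees *exactly* with an independent scalar
implementation at the same Δt, and that the regular-spiking cell's
firing rate is insensitive to step refinement (±1 spike/s against a
0.01 ms reference).  The fast-spiking cell is not: at I = 5.25 µA it
sits near its saddle-node bifurcation, where the interspike interval
is strongly step-size dependent (43 spikes/s at 1 ms vs 50 at 0.01 ms).
This is an inherent property of 1 ms Euler on these equations, not a
defect of the loop; all headline results are defined at Δt = 1 ms.

### Initial conditions

Membrane potentials start uniformly in c ± 5 mV (`v0_spread = 10`),
with u = b·v and gates at zero.  Starting every cell at exactly v = c
is *not* innocuous: the perfectly synchronized start decays through
long-lived collective transients (~0.9 s) and favors rigid
cluster states.  A few millivolts of initial spread removes both
artifacts — the gamma envelope then settles within ~0.4 s — while
leaving the stationary rhythm unchanged.  The first second of every
trial is discarded before analysis regardless.

### What the network does

Under constant drive (12.25 µA to E, 5.25 µA to I) the network
oscillates at ≈48 Hz.  The E cells cannot follow every cycle — the
regular-spiking adaptation increment d = 8 caps their sustained rate
near 25 Hz — so individual E cells fire on alternate cycles while the
I population fires every cycle.  The mean field therefore contains,
besides the ~48 Hz rhythm, a subharmonic near 24 Hz whose size depends
on how rigidly the E population splits into two alternating clusters.
For this reason the experiment runners report peak frequencies within
a gamma analysis band (30–100 Hz by default): for small networks and
some off-default current pairs the subharmonic carries more raw power
than the gamma peak, while every frequency the study design cares
about lies in the gamma range.  Entrainment analyses instead search
the full 5–100 Hz band, since there the output must be free to follow
the drive.

Known limitation: with the published parameters the resonance is not
as drive-independent as described.  The pair (12.75, 7.25) µA keeps a
gamma-band peak at ~50 Hz, but (8.75, 5.25) µA slows the network to
~36 Hz — the E-cell recovery, not the GABA decay, is rate-limiting at
that drive.  Likewise the dominant-frequency dependence on c_ii is
weak here (~0.2 Hz over 0.002–0.008).  Both are reported as measured.

## Stimuli

Three drive shapes, all delivered identically to every E cell with a
constant I-cell drive: constant; broadband (one fresh uniform noise
sample per integration step; "amplitude A" means zero-mean
Uniform[−A/2, +A/2] by default, so the operating point stays at the
constant-drive value — dialects Uniform[0, A] and Uniform[−A, A] are
selectable); and sinusoidal (i₀ + A sin 2πft).  The broadband noise
trace is stored on the train so TRF estimation regresses against
exactly the delivered input.

Luminance flicker for the synthetic MEG channel is i.i.d. Uniform[0,1]
at 1440 Hz (a high-refresh projector), zero-order-held to the 1000 Hz
analysis rate, reproducing the rate mismatch of a real recording.

## TRF estimation

Ridge regression `TRF = (SᵀS + λI)⁻¹ Sᵀx` with λ = 1 on raw
(mean-centered, unscaled) units.  S is the lagged stimulus matrix
(zero-padded at trial edges); the first and last lag-window of every
trial is excluded from the normal equations to avoid pad bias; normal
equations are accumulated over trials and over chunks of long
recordings, and the system is solved with a symmetric
positive-definite solve.  Default lag windows: −100…300 ms for model
TRFs, −50…350 ms (or longer) for synthetic MEG work.  Band-limited
views use zero-phase (forward–backward) 6th-order Butterworth filters;
order 6 keeps double-filtering within 1 % of single-filtering in the
passband while attenuating a 10 Hz component by >10⁵ in the
40–100 Hz band.

### Echo frequency

`echo_peak_frequency` estimates the dominant frequency of the
band-limited echo from the zero-padded power spectrum of the windowed
kernel (default window 0–160 ms, where the gamma echo lives and the
alpha echo has not yet begun).  Three refinements matter at realistic
signal-to-noise:

1. the filter uses a guard band 15 Hz wider than the search band, so
   its skirt does not attenuate echoes near the band edge;
2. a linear noise floor (fitted away from the peak) is subtracted and
   the peak localized as a power centroid over ±6 Hz, suppressing the
   tilt of the 1/f estimation-noise floor;
3. the spectral peak of a damped oscillation sits below the
   oscillation frequency by the damping shift — for
   A e^(−t/τ) sin(2πf₀t) the power peak is at √(f₀² − γ²), γ = 1/(2πτ)
   — so γ is estimated from an amplitude-weighted fit to the log
   Hilbert envelope and the peak corrected as √(f_peak² + γ²).
   The amplitude weighting makes the fit track the echo where it is
   strong and ignore the noise floor, and reduces to the plain fit for
   long-decay echoes.

On noiseless kernels this estimator is accurate to ≈0.2 Hz across
42–58 Hz; its remaining error at low signal-to-noise is estimation
noise, addressed by design (more data / repeated recordings), not by
further estimator tuning.

### Echo decay

`decay_time` fits a line to the log Hilbert envelope of the band-
limited kernel past its peak and reports −1/slope.  A fixed-threshold
(1/e crossing) alternative is provided but is not the default: the
crossing saturates at the first envelope minimum once the TRF noise
floor is reached, and was insensitive to drive amplitude where the
fitted constant resolves the expected ordering (decay shortens
monotonically as broadband amplitude grows from 2 to 9 µA).

## Spectral analysis

Welch PSDs use 1 s Hann segments with 50 % overlap (1 Hz resolution)
and constant detrending; trial averaging averages the per-trial PSDs.
Printed frequencies are therefore matched at ±2 Hz in full-scale
checks (±3 Hz in the reduced-trial fast suite).  The time–frequency
transform uses Hann windows spanning 5 cycles of each analysis
frequency (5–100 Hz by default), amplitude-normalized so a unit tone
yields unit power at its own frequency regardless of window length —
without this normalization the frequency-dependent window length tilts
ridges toward lower frequencies.  Windows that do not fit inside the
signal are masked, not shrunk.  Relative power change is
(P_st − P_bl)/(P_st + P_bl), masked where both are zero.

## Synthetic MEG generator

The generator emulates a single posterior sensor responding to
broadband flicker: the flicker train convolved with a ground-truth
kernel (damped gamma echo: 48 Hz, 40 ms onset, τ = 20 ms, 2–3 visible
cycles; damped alpha echo: 10 Hz, 200 ms onset, τ = 300 ms, up to ~10
visible cycles, half the gamma amplitude) plus 1/f background noise
and an optional 50 Hz line component with per-trial random phase.
Signal-to-noise is the ratio of kernel-response variance to noise
variance in 1–100 Hz; the default 0.1 emulates a weak cortical
response.  Since the alpha echo dominates the kernel-response
variance, the *gamma* echo's effective SNR is considerably lower
still, which is why recovery benefits from recording lengths in the
hundreds of seconds — comparable to the ≈140 4-s trials a real session
yields.  Parameter recovery at the default SNR uses the median of
five 360 s recordings per condition; recovered gamma frequencies over
44–56 Hz are then within ±1 Hz and unaffected (≤1 Hz) by line noise.

What the generator does *not* emulate: sensor topography and source
mixing, non-stationary alpha power, eye-movement and muscle
artifacts, and trial-boundary effects.  Passing recovery tests
therefore validate the TRF/spectral stages' correctness and
calibration, not robustness to those real-data complications.

## Experiment runners and reproducibility

Each runner (constant current, current grid, size sweep, broadband
echo, oscillatory grid, inhibitory-connectivity sweep, transient) is
deterministic given its master seed: the seed expands through
`numpy.random.SeedSequence` into independent streams per trial, and
within a trial into (connectivity/initial conditions, stimulus noise),
so trials differ only where the protocol says they differ.  Defaults:
8 s simulated per trial, first 1 s discarded, 20 trials at full scale
(the reduced suite uses 5–10 trials with ±3 Hz tolerances).  The
transient estimator band-passes the mean field at 40–60 Hz, smooths
the Hilbert envelope over 200 ms (several gamma cycles), takes the
1–3 s mean as steady state, and reports the first time the envelope
enters and stays within ±20 % of it; it returns NaN when there is no
steady oscillation.  The entrainment threshold is the smallest drive
amplitude from which the trial-averaged output peak equals the drive
frequency (±2 Hz) at every tested frequency ≥ 20 Hz, for that
amplitude and all larger ones; the tested frequencies extend to
100 Hz because following is hardest at the top of the range — a grid
stopping at 90 Hz understates the threshold by ~1 µA.

Numerical edge handling worth knowing: a NaN membrane potential
aborts the simulation naming the first offending cell and time; a
singular lagged-stimulus system at λ = 0 raises with advice to use
λ > 0; `echo_peak_frequency` refuses kernels with <1 % of their
windowed power in the requested band (e.g. a pure alpha kernel probed
in the gamma band).
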