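# Methods

## Encounter-rate model

The plume is not simulated as fluid dynamics; the model *is* the
expected detection rate of an advection–diffusion plume with finite
particle lifetime:

    R(r | r0) = (a E / d) · exp(−d/λ) · exp(s W / 2D),
    λ = sqrt(D τ / (1 + W² τ / 4D)),

where `d = |r − r0|` clamped below by the sensor size `a` (the rate is
then finite everywhere, including at the source), and `s` is the signed
downwind displacement of the searcher from the candidate source.  All
internal computation is SI (metres, seconds); trajectories are stored in
millimetres, the unit of the raw tracking data, and converted at the
boundary.

Defaults: `a` = 0.01 m, `E` = 1, `τ` = 6.3 s, `D` = 0.057 m²/s,
`W` = 0.6 m/s, wind blowing along +x, source at the origin.  `τ` and
`D` are dimensionless in their original usage; we read them in SI units,
which yields λ ≈ 0.181 m at `W` = 0.6 m/s — a plausible plume scale for
a 1.5 m arena — and near-source rates of order 1 /s, consistent with a
1 Hz pulsed release.  Sign convention: with these parameters
`W/2D < 1/λ`, so the rate decays in every direction but most slowly
downwind, which is where a real plume extends.  A unit test pins this
orientation.

## Likelihood, posterior, entropy

Detections are an inhomogeneous Poisson process in time along the
searcher's path.  For each candidate source cell,

    log L = −∫ R(r(t′) | r0) dt′ + Σ_i ln R(r(t_i) | r0),

the integral running over the whole observation window (detection
instants have measure zero, so this equals the sum over the silent
intervals).  The integral is a trapezoid rule at the trajectory sampling
times; halving the sampling interval moves log L by well under 0.1%, so
trajectories may be decimated (the pipeline integrates at 20 Hz by
default).  Likelihoods live in log space throughout; the posterior is a
max-shifted softmax (60 s of integrated rate underflows a linear-space
product badly).  The prior is uniform over the grid.

Entropy is the discrete Shannon entropy over grid cells (0·ln 0 := 0).
This differs from a differential entropy by +ln(cell area), a constant
at fixed resolution; since results are reported as the ratio S_t/S_0
with S_0 = ln(n_cells) the entropy of the uniform prior, the constant is
immaterial, and S_rel = 1 exactly at the window start.  The grid default
is the 1.5 × 1.5 m arena at 10 mm resolution (the sensor size);
analyses in tests use smaller grids around the source for speed, stated
per test.  The source estimate is the maximum-probability cell center,
ties broken to the lowest row-major index; the posterior mean is a
reasonable alternative but the mode matches how estimated-source maps
are usually drawn.  Entropy traces recompute the posterior from the
truncated history at each evaluation time (batch form); this is
algebraically identical to recursive updating under the product-form
likelihood and much easier to verify — a test asserts trace/batch
equality to 1e-9.

## EAG processing

Physiological EAG deflections are negative-going; all analysis first
multiplies by a configurable polarity (default −1) so responses are
positive "amplitudes".  Conditioning is a zero-phase (forward–backward)
4th-order Butterworth low-pass at 10 Hz — zero-phase so that peaks are
not delayed by filtering; the effective magnitude response is the
squared 4th-order characteristic.

Encounter timing is peak detection on the filtered response signal:
prominence threshold defaulting to 5× the median absolute deviation of
the trace (a robust noise estimate while responses are sparse) and a
0.3 s minimum separation (the stimulus period is 1 s).  A subtlety: the
filtered peak lags true odor arrival by ≈ 40 ms — the kernel's own
rise-to-peak plus the symmetric smearing of its asymmetric shape.  For a
characterized response kernel this latency is computable
(`synthetic.filtered_peak_lag` filters the kernel and locates its peak);
`detect_encounters(..., peak_lag_s=...)` subtracts it so reported times
estimate odor arrival.  The in-vivo analogue is a static single-puff
calibration of the preparation.  With the correction, detection at
SNR 10 recovers encounter times within a few milliseconds.

Response metrics: baseline is the median of the 0.2 s before stimulus
onset; amplitude is the peak deviation within a 0.5 s search window; Tr
is onset→peak; Td is the first return to within ±5% of amplitude of
baseline.  A peak deviation below 0.05 mV is a no-response result
(`None`), not an error.  Intensity is min–max normalized per trial
(all-equal amplitudes map to 1).  The near-source ratio is the amplitude
of the single encounter nearest the source divided by the trial maximum
— in [0, 1], scale-invariant, and below 1 whenever adaptation has set
in near the source.

## Synthetic data

The generator's defaults are the standard free-walking assay: source at
the origin, 1 Hz odor pulses (0.2 s on / 0.8 s off) into a 0.6 m/s wind,
moth starting at (150, 0) mm, success within 10 mm, 180 s timeout,
100 Hz control/tracking rate.

**Encounters** are drawn from R by Poisson thinning (global majorant
1.5× the sampled maximum; the closed-loop agent uses the per-step
Bernoulli equivalent p = 1 − exp(−R dt)).  A chi-square test against the
analytic Poisson count law at constant rate guards the sampler.
Gating encounters to the pulse schedule (delayed by the advection time)
is available but off by default, since the likelihood assumes ungated
Poisson statistics.

**The agent** follows the walking-silkmoth behavioral program.  A fresh
encounter triggers a straight fast upwind SURGE (2.5 s at 30 mm/s,
heading jitter 0.08 rad); the surge decays into a crosswind CAST (1 s of
zigzag with growing half-period) and then into a LOOP — an orbit of
growing radius (20 → 70 mm at constant 15 mm sweep pitch) around an
anchor placed 40% of the way back along the last surge.  Two mechanisms
beyond the plain surge/cast sketch proved essential and are grounded in
the observed biology: (1) *looping* as the lost-behavior stage keeps the
agent near where it lost the plume and systematically sweeps the
surrounding annulus, instead of random-walking away; (2) *adaptation
gating* — the agent carries a depression/recovery state (ρ = 0.6 per
encounter, 5 s recovery) and only surges when that state exceeds 0.85.
Far from the source (encounters every ~10 s) the state stays high and
every encounter drives an upwind surge; near the source (encounters
every ~2 s) it equilibrates low, fresh surges stop, and the loop sweep
finds the 10 mm disc.  Without the gate the agent ratchets upwind past
the source indefinitely, because this rate model, unlike a real plume,
leaks odor upwind.  Adapted contacts re-anchor the loop at the contact
point.  Speeds are capped at 32.8 mm/s and turn rate at 1.0 rad/s at
every step (asserted in tests); casting before the first-ever encounter
routes its turns through the downwind side, so an unstimulated moth
shows < 30% upwind movement.  Under the defaults the agent reaches the
source in about 79% of 180 s trials with a mean time-to-source around
27 s; these parameters are a modeling choice tuned for a competent
generator, not a biological claim.

**The EAG synthesizer** renders v(t) = polarity · Σ A_i g(t − t_i) +
noise + drift at 1 kHz, with g a peak-normalized difference of
exponentials (rise 2 ms, decay 150 ms; onset-to-peak
τ_r τ_d/(τ_d−τ_r)·ln(τ_d/τ_r) ≈ 8.7 ms, inside the < 10 ms response-time
envelope, recovery ≈ 0.45 s > 100 ms).  A 3 ms rise would peak at 12 ms
and violate that envelope, which is why 2 ms is the default.  Amplitudes
follow the depression/recovery recursion
s ← 1 − (1 − s·ρ)·e^(−Δt/τ_rec) with ρ = 0.7 and τ_rec = 5 s: at 1 Hz
the sequence decreases strictly to the fixed point
(1 − e)/(1 − ρe) ≈ 0.4246 (e = e^(−1/5)), and a 6 s silent gap restores
≈ 91% of the initial amplitude.  Noise is white Gaussian (default
0.02 mV; SNR is A0/σ) plus a slow sinusoidal baseline drift (0.05 mV,
30 s period, random phase) standing in for electrode drift.

What the generator does *not* emulate: real filament-scale plume
intermittency and meander, concentration-dependent EAG amplitude
(amplitude here reflects adaptation state only), sensor motion artifacts,
inter-individual variability in speed and response gain, and any
vision- or mechanosensation-driven behavior.  Passing tests therefore
show that the *analysis* is correct under its own statistical
assumptions, not that those assumptions exhaust real moth data.

## Kinematics

Fusion interpolates positions onto a uniform 0.01 s grid (the camera
period) and carries each encounter's amplitude/intensity forward by
zero-order hold (0 before the first).  Speed is a central difference
smoothed over 0.1 s.  Wind-frame classification uses 45° half-width
sectors around the upwind and downwind directions, time fractions over
samples moving faster than 2 mm/s (stationary jitter has no meaningful
heading).  Whether such fractions should be over time, distance, or
encounters is a genuine open choice; time fractions are used and stated
in outputs.  Cast detection is an operational definition — a 3 s window
with ≥ 2 crosswind-velocity sign reversals and net upwind progress
< 20% of path length — with every threshold exposed in the API.
Localization is first passage into the success disc before the timeout.

## Fixture and problem sizes

Source-recovery checks use a boustrophedon survey (±30 mm, 8 mm line
spacing, 40 mm/s, 60 s) on a ±120 mm grid at 10 mm cells: under the
default plume this collects ~24 encounters and the posterior mode lands
within 2 cells of the truth in ≈ 98% of seeded runs.  Wider surveys
starve the estimator (< 10 encounters in 60 s) — an honest property of
the rate model at E = 1, not of the estimator.  Entropy-reduction
checks use 20 simulated trials on a 35 × 30 cm grid with the trajectory
decimated to 20 Hz and 21 evaluation times; the acceptance script uses
30 trials for behavioral statistics and 50 for detection statistics.
All randomness flows from explicit integer seeds; no global RNG state
is touched anywhere.

## Known limitations

- The distance clamp d ≥ a makes the likelihood insensitive within one
  sensor size of a candidate cell; with 10 mm cells this is invisible at
  the reported resolution.
- The posterior mode on a grid quantizes estimates to cell centers; the
  source at a cell corner makes ~7 mm the best achievable error.
- The behavioral controller is a caricature tuned for competence; its
  success rate and time-to-source should not be read as predictions for
  live animals.
- `near_source_ratio` uses the single nearest encounter; with very few
  encounters it is high-variance.
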