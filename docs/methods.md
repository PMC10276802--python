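# Methods

## Model and assumptions

The core object is the finite-N Kuramoto system with all-to-all sinusoidal
coupling,

    dtheta_i/dt = omega_i + (K(t)/N) * sum_j sin(theta_j - theta_i),

integrated either with constant K or with K following logistic growth
`dK/dt = a*K*(1 - K/C)`. The logistic schedule encodes the assumption that
seizure severity — and with it the effective coupling among neuronal
populations — rises along an S-shaped curve after a convulsant is
administered: slow onset, rapid escalation, saturation at a carrying
capacity C chosen above the critical coupling so the system must
eventually lock. Each oscillator stands in for one spectral component of a
basal EEG (interpreted as a population firing at that frequency);
amplitudes are constant in time, so all dynamics live in the phases.

Coherence is tracked by the order parameter `r*exp(i*psi) = mean(exp(i*theta_j))`
and the locking threshold by the finite-N critical coupling

    K_c = N*(w_max - w_min) / (2*(sin(g) + (N-2)*sin(g/2))),
    g   = 2*arccos((-(N-2) + sqrt((N-2)^2 + 32)) / 8),

which reduces to the classic two-oscillator threshold |w_2 - w_1| at N = 2
and vanishes when all frequencies coincide. Above K_c the locked state is
generally *partial*: with the reference ensemble, thirteen components lock
while the 119.93-Hz gamma component stays drifting (its offset from the
mean frequency exceeds K*r), which is why r oscillates in a high band
instead of approaching 1.

### Frequency convention

Natural frequencies enter the ODE numerically as the selected Hz values,
not multiplied by 2*pi. This is a deliberate design choice: the critical
coupling scales linearly with the frequencies, and the reference threshold
K_c = 69.02359 (with C = 75 chosen just above it) is consistent only with
the Hz-as-omega reading — under a rad/s convention the same ensemble would
need K_c ≈ 433.7. The pipeline exposes `frequency_units = "hz" | "rad_per_s"`
for users who want physically scaled phase velocities; every threshold and
schedule then scales accordingly. A consequence is that simulated phases
evolve in *model time*: a component of f Hz completes f/(2*pi) cycles per
model-second. The reconstruction module therefore keeps two explicit
modes — dynamic (simulation phases, model time) and static
(2*pi*f*t + phi, physical time) — rather than silently rescaling one onto
the other.

## Spectral selection

The one-sided amplitude spectrum uses the cosine convention
`A_k = 2|X_k|/M`, phase = arg(X_k), so an on-bin tone is recovered exactly
and the inverse is literally the cosine sum `A_0/2 + sum A_k cos(.)`. The
DC entry keeps the sign of the mean (a cosine at zero frequency has no
phase slot to carry it); the Nyquist bin of an even-length window is not
doubled and participates in its band normally.

Bands are dyadic in *bin index*: B_0 = {1}, B_n = (2^(n-1), 2^n], bins
above 2^n_max discarded; the per-band candidate is the bin of maximum
amplitude, ties broken toward the lowest bin (deterministic). This gives
floor(log2(floor(M/2))) + 1 candidates — 14 for a 60-s window at 300 Hz —
and doubling the window length adds exactly one. The argmax-per-band rule
and its tie-break are this package's design choice where the convention
was genuinely open; they are validated by the property that any tone
dominating its band is selected with exact frequency.

## Coupling schedule and calibration

The logistic coupling is propagated by its closed form

    K(t) = C / (1 + ((C - K0)/K0) * exp(-a*t)),

numerically safer and cheaper than co-integrating the K ODE; the
co-integrated route is retained as a test oracle (agreement to 1e-8
absolute over the full 2580-s horizon). Defaults: a = 0.0065 per
model-second, C = 75, K0 = 0.00718. The initial value K0 is not a measured
quantity; it is calibrated once, by closed-form inversion, so that K(t)
crosses K_c = 69.02359 at t = 1800 s — the onset timing of the reference
scenario. `coupling_crossing_time` exposes the same inversion as a
diagnostic.

## Integration

`scipy.integrate.solve_ivp` with DOP853 and rtol = atol = 1e-8 by default.
The coupling sum is evaluated through the exact mean-field identity
`(K/N)*sum_j sin(theta_j - theta_i) = K*r*sin(psi - theta_i)` (O(N) per
right-hand-side call; algebraically identical for all-to-all coupling).
Initial phases default to zero — the reference conditions are then fully
deterministic, and the asymptotic locked state does not depend on the
initialization — with an optional seeded uniform(-pi, pi] draw. Output is
sampled on a uniform grid (default 1 sample per model-second; denser grids
are only needed when the reconstructed signal itself is of interest).
Phases are reported unwrapped (they are the integrated state, never
wrapped). Degenerate coherence (r numerically 0, mean phase undefined) is
reported as psi = 0 with a flag rather than an error.

Refinement stability is tested: halving the tolerances moves the
final-window mean of r by less than 1e-3 on the reference run. The
final-window *minimum* of r (sampled at 1 Hz) is the robust summary of the
locked band; the upper envelope of r(t) depends on how a fast beating
waveform is sampled and is reported as a diagnostic only.

## DTW

Local cost |x_i - y_j|; accumulation
`D(i,j) = min(D(i-1,j-1) + 2d, D(i-1,j) + d, D(i,j-1) + d)` (the symmetric
step pattern with diagonal weight 2 — the documented default of the
standard DTW packages), no global window. Total cost is normalized by
n + m. Backtracking prefers the diagonal, then the i-decrement, so paths
are deterministic. The path-linearity diagnostic is the coefficient of
determination of the path's j-coordinates against the straight line from
(0,0) to (n-1,m-1), clamped to [0, 1]; identical series score 1 and an
L-shaped path scores low. The DP is verified against exhaustive
enumeration of every admissible warping path on short sequences — an
oracle that shares no code with the recurrence. A memory guard (default
2e8 cells) refuses infeasible cost matrices with advice to block-mean
decimate (`downsample`); full-resolution alignment of two 774,000-sample
series is out of reach by design, and DTW comparisons are treated as
qualitative diagnostics, not calibrated statistics.

## Synthetic data

`generate_basal` emulates a resting cortical recording as the static
reconstruction of a component set (default: the packaged 14-component
table) plus additive white Gaussian noise, seeded; the default noise SD is
10% of the largest component amplitude — enough to be visible, small
enough that every generating tone remains its band's maximum.
`generate_seizure_like` is a single large cosine plus optional noise, the
caricature of a fully synchronized ensemble. The repeating-decimal
frequencies of the packaged table are stored via their bin indices and
reconstructed as exact multiples of 1/60 Hz, so all tones are on-bin for a
60-s window and selection inverts generation exactly (frequencies) and to
1e-6 (amplitudes, phases). The table carries no DC term, so the fixture's
A_0 is 0.

What the generators do **not** emulate: 1/f background spectra, movement
artifacts, non-stationarity, multi-channel structure. Tests passing on
synthetic data therefore demonstrate correctness of the algorithms and
self-consistency of the pipeline, not performance on real EEG; on a real
recording the per-band argmax can land on broadband background rather than
a narrowband rhythm.

## Problem sizes and defaults used in checks

The shipped checks run the reference scenario at its native size: N = 14
oscillators, 2580 model-seconds, output at 1 Hz (the heavy run takes tens
of seconds); selection operates on the full 18,000-sample window. DTW
oracle checks use sequences of length ≤ 8, where exhaustive path
enumeration is exact and fast; pipeline-level DTW demonstrations decimate
to a few hundred samples, consistent with treating DTW as a qualitative
diagnostic.

## Known limitations

- All-to-all coupling with a single global K(t); no network topology,
  per-pair couplings, or frequency adaptation.
- Constant amplitudes: the reconstruction cannot express amplitude growth
  during a seizure, only phase alignment.
- The model-time/physical-time dichotomy of the Hz-as-omega convention is
  documented, not resolved; comparing a dynamic reconstruction against a
  physical-time recording requires choosing an axis mapping.
- The locked-state upper envelope of r(t) is sampling-sensitive; only its
  floor is treated as a stable result.
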