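# Methods

## Stimulus representation

All spectral computations live on a log2-frequency axis in octaves re
1 kHz, 0.005-octave steps, spanning 1–256 kHz. The step is ≥10× finer than
any stimulus edge feature and the range covers the widening skirts of the
widest stimuli. Responses use the step as integration measure, so grids of
different resolution agree (checked to 1e−3 relative between 0.005 and
0.0025-octave axes).

A broadband stimulus (BBS) with center frequency f_c and full bandwidth b
(octaves) occupies [f_c·2^(−b/2), f_c·2^(b/2)]; bandwidth is split
symmetrically because the edge-frequency analysis defines f_t and f_b
symmetric about f_c. Its spectrum vector is a height-1 rectangle with
linear half-octave skirts on each edge — a deliberately crude stand-in for
peripheral (cochlear) filter spread that adds no free parameters. Pure
tones are the b → 0 triangle of the same construction: the continuity with
BBS vectors matters more than the exact pure-tone shape, since pure tones
are excluded from fitting anyway. A notch stimulus is the complement of a
BBS within a global band (2 kHz up to one octave above the highest pure
tone, both configurable); its ramps descend into the notch so that a BBS
and its complementary notch sum exactly to the band profile.

Waveforms are sums of equal-amplitude cosines spaced 0.001 octave with
uniform random phases (seeded per condition and trial), 100 ms long with
5 ms linear ramps, synthesized at 500 kHz. A single scalar calibrates
amplitude to sound level: a pure tone at unit component amplitude defines
55 dB SPL, and all levels are computed from waveform RMS against a
ramp-matched pure-tone reference (each linear ramp carries 1/3 of the
plateau power, so the reference includes the factor 1 − 4·ramp/3·duration).
Because spectrum level is fixed, total level grows with bandwidth: a
1-octave BBS (1001 components) measures 10·log10(1001) ≈ 30 dB above the
pure tone.

## The MRW tuning curve

    MRW(f) = A · (w² − IE·(f−μ)²) · exp(−(f−μ)²/2w²) · φ*(f)
    φ*(f)  = (0.5 + 0.5 s)·Φ(f; μ, σ) + (0.5 − 0.5 s)·(1 − Φ(f; μ, σ)),  σ = w/2

Parameters, units, defaults:

| parameter | meaning | range |
|---|---|---|
| μ | best-frequency position, octaves re 1 kHz | presented frequency range |
| w | width, octaves | ≥ 0.05 |
| IE | inhibition/excitation ratio (0 Gaussian … 1 Ricker) | [0, 1] |
| s | skewness; ±1 keeps one inhibitory flank only | [−1, 1] |

The sign in the polynomial factor is forced by the stated limits: IE = 1,
s = 0 must give the classic Ricker wavelet and IE = 0 a Gaussian (both hold
bin-for-bin to 1e−9 on the default axis). The sigmoid width σ = w/2 is a
heuristic choice exposed as a module constant (`PHI_SIGMA_FRACTION`); note
that with a CDF-based φ* the suppressed flank retains a small tail — at
s = 1 roughly 0.3% of the peak leaks into the lower lobe — so "one-sided"
inhibition is accurate to that order, not to machine precision.
Normalization A is computed numerically over the axis (no closed form once
s ≠ 0). Responses are max(0, Σ curve·stimulus·Δoct); the rectifier encodes
the low spontaneous rate of cortical units.

## FBRAs from spikes

Evoked rate per condition = mean over trials of (stimulus-window count −
preceding-baseline count)/window, windows 100 ms each, 10 trials per
condition by default. The responsiveness screen is a one-tailed paired
t-test (stimulus > baseline) per condition, Bonferroni-corrected over all
conditions of the grid, and requires a significant excitatory ON response
to at least one broadband (b > 0) condition; inhibited-only or
pure-tone-only units fail. Zero-variance differences get p = 1 when the
mean difference is ≤ 0 and p = 0 (logged) when all differences are
positive. A further "highly responsive" cut requires a peak evoked rate of
5 spikes/s by default; the exact value the original screen used is not
documented, so it is a config knob. OFF responses are ignored throughout;
trials with missing baselines are dropped, not imputed.

## Fitting

Objective: −Pearson r between neuronal and model FBRAs over the b > 0
cells, plus 0.05·w. If rectification flattens the model FBRA to a
constant, the correlation term is defined as 0 — finite, and penalizing a
non-informative model without letting the width term dominate. Zero
variance in the neuronal FBRA refuses the fit outright.

Bounds (μ in the presented range, w ≥ 0.05 oct, IE ∈ [0,1], s ∈ [−1,1])
are enforced by the sinusoidal transform p = lo + (hi−lo)(sin z + 1)/2
inside an unconstrained Nelder–Mead — the standard construction for a
bounded simplex search. w needs a finite upper bound for the transform;
2.0 octaves is safe because the width penalty makes larger widths strictly
worse than anything the restarts reach. Tolerances 1e−4 on parameters and
objective, ≤ 2000 evaluations per restart; all diagnostics land in
`FitResult`.

The correlation landscape is multimodal, so the search starts from a grid:
μ at each presented center frequency × w ∈ {0.1, 0.4} × IE ∈ {0, 1} ×
s ∈ {−1, 0, 1}. Polishing every start point is wasteful — the objective is
first evaluated at all of them, and the best `n_restarts` (default 12) are
polished, selected best-per-(IE, s)-corner first so every basin family
gets at least one simplex run. On a 50-unit synthetic population this
selection matches polishing all 132 starts. Fits are bit-reproducible
given (data, config).

The shuffle control permutes all cell values uniformly across the grid
(read of "randomizing the location of each of the 121 mean responses" as
an unrestricted permutation), refits, and averages r over `n_shuffles`
(default 100; reduce for exploratory runs — the intact-vs-shuffled gap is
enormous relative to the shuffle-to-shuffle spread).

### Recovery properties and known biases

Two systematic effects of the width penalty are worth knowing:

- For Gaussian-like units (IE ≈ 0) the correlation surface is flat in w
  (curvature c ≈ 0.4), so the penalized optimum sits at w_true − 0.05/(2c),
  an underestimate of 0.05–0.10 octaves even on noiseless data. Ricker-like
  units (c ≈ 1–2) recover w well within 0.05.
- At 10 Poisson trials, mid-IE units (IE ≈ 0.5–0.8) can be fit marginally
  better — in penalized objective, not in r — by a narrower IE = 0
  Gaussian; fitted IE then collapses to 0. This is a property of the
  objective, not of the optimizer (polishing every restart start finds the
  same optimum). Fitted IE is therefore most trustworthy near its
  extremes, which is also where the synthetic and recorded populations
  concentrate.

## Edge analysis

Quadrants over (s, IE) with cuts s_cut = 0, ie_cut = 0.5 (boundaries → the
higher quadrant by the ≥ convention). The cuts are not canonical — they
are placed between the two described clusters (IE ≈ 0 vs IE ≈ 1) and are
config options. Edge tuning fits regress all cell responses (pure tones
included, with f_t = f_b = f_c) on log2 edge frequency with a Gaussian
(amplitude, mean, sd); an additive offset is available behind
`fit_offset` but defaults to off. R² = 1 − SSres/SStot, clipped at 0;
zero-variance scatters are flagged degenerate rather than fit. The
population test compares ΔR² = R²_t − R²_b between Q1 and Q2–Q4 units with
a two-sample t-test, skipped with a notice when a group has < 2 units.

## Synthetic populations

Each unit: stim_count ~ Poisson((baseline + gain·response)·window),
pre_count ~ Poisson(baseline·window) — the minimal count noise model; a
negative-binomial (gamma–Poisson) option sits behind `overdispersion` for
checking sensitivity to extra-Poisson variability. Only window counts are
simulated; within-trial spike timing (ON-transient shape) is not, so PSTH
shape carries no information here.

Population defaults emulate the parameter ranges reported for deep-layer
mouse auditory cortex: μ truncated-normal 10.5 ± 9.4 kHz within the
presented range, w truncated-normal 0.26 ± 0.25 octaves floored at the
0.05 bound, a 60/40 mixture of Q1-like draws (IE ∈ [0.6, 1], s ∈ [0.4, 1])
and Q2-like draws (IE ∈ [0, 0.2], s ∈ [−0.3, 0.3]), per-unit gains
log-uniform 20–200 spikes/s (per unit model response) and baselines
uniform 0.5–5 spikes/s. With these conditions the fitted-correlation
distribution spans roughly 0.3–0.98 (median ≈ 0.93).

What the generator does not emulate — and hence what passing tests do not
show about recordings: non-Poisson trial-to-trial correlations, adaptation
across the session, OFF responses, temporal response structure, and units
whose tuning is simply not in the MRW family. Recovery results here bound
what the pipeline can do when the model is true.

## Problem sizes

Simulation-backed checks run at desk scale, chosen to finish comfortably
on one CPU: 50-unit populations at 10 trials for recovery/shuffle/notch
statistics (with 2 shuffles per unit — sufficient because the
intact-vs-shuffled gap is scored by a paired sign test), 30-unit
populations across trial counts {5, 10, 40} for the recovery curves, and
10 phase draws for level calibration.

## Known limitations

- The model is spectrally static; temporal dynamics are out of scope.
- Pure-tone responses are systematically under-predicted (they are the
  lowest-intensity stimuli under fixed spectrum level) and are excluded
  from the fit, matching the source protocol.
- The s parameter is weakly identified when IE ≈ 0 (it only tilts a
  Gaussian), so quadrant labels of low-IE units are noisy around the
  s_cut boundary.
- Units with μ near the top of the presented range have their upper
  sideband outside the probed grid; IE and s are then unidentifiable in
  principle.
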