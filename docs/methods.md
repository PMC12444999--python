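# Methods

This note documents the models, statistical procedures and numerical
choices behind `promyelin`, and what its synthetic data can and cannot
establish about real recordings.

## Channel models

Eight extracellular channels (A–H) recorded over a proteinoid–myelin
hybrid network each follow a characteristic phenomenological form.  The
package simulates each as a **deterministic skeleton** plus **stochastic
components**; with the stochastic amplitudes zeroed, the trace equals the
skeleton exactly, which anchors the deterministic unit tests.

| ch | skeleton | key defaults |
|----|----------|--------------|
| A | baseline +25 mV decaying to −40 mV by 40 ks (exp, τ=8 ks) | fluctuation sd 5 mV (τ 5 ks); Poisson spikes, rate 0.02 /s, amplitude U(10, 15) mV, exp kernel, 20 s half-life |
| B | linear drift −25 → +25 mV over 40 ks (α=+1.25 mV/ks); plateau with 5 mV oscillation, period sweeping 2000→3000 s; step to +40 mV at 160 ks (1 ks ramp) | sd 2.5 mV |
| C | linear drift β=−2 mV/ks to −75 mV at 37.5 ks, slow settle to −80 mV | sd 2.5 mV |
| D | exp hyperpolarization to −55 mV (τ₁=200 s), recovery γ=+0.2 mV/ks | sd 2.5 mV |
| E | −5 + 75·exp(−t/20 ks) mV, so V(0)=+70 mV and V(∞)≈−5 mV | sd 2.5 mV |
| F | −60 mV baseline; smooth dip to −90 mV (20–30 ks); linear recovery α=+0.6 mV/ks returning to −60 mV at t_c=80 ks; switch to +35 mV | sd 7.5 mV; t_c and post-level configurable (alternative readings: 90 ks, +40 mV) |
| G | −70 → +20 mV by 10 ks; baseline ≈+10 mV; 15 mV raised-cosine oscillation burst 23–36 ks (period 2 ks); pulse to −30 mV at 150 ks (5 ks wide); endpoint 0 mV | sd 5 mV |
| H | −50 + 73·(1−exp(−t/20 ks)) mV to 100 ks, then β=+0.15 mV/ks reaching ≈+34.5 mV | sd 2.5 mV |

Notes on genuinely open choices:

* **Channel A baseline** between 0 and 40 ks is not specified beyond its
  endpoints; a smooth exponential interpolation is used.  The spike *rate*
  is likewise unspecified; 0.02 events/s is chosen so the mean inter-spike
  interval (~50 s) matches the reported ISI scale for this channel.
* **Channel B oscillation periods** are described as 2000–3000 s.  They are
  realized as a deterministic period sweep across that band rather than
  random draws, so that the noise-free trace is a reproducible skeleton
  (a random-period oscillation would make "noise off" seed-dependent).
* **Channel D** carries an internal tension: recovery at 0.2 mV/ks from
  −55 mV cannot reach the quoted −15 mV steady level within 180 ks; the
  printed rate is kept (it is the explicitly parameterized quantity) and
  the trace ends near −19 mV.
* **Channel F** combines four printed statements (−60 mV baseline for
  t<30 ks; minimum −90 mV during 20–30 ks; recovery 40–80 ks at 0.6 mV/ks;
  piecewise −60/+35 mV switch at t_c).  The implemented geometry — dip
  20–30 ks, recovery 30–80 ks ending exactly at the −60 mV baseline —
  satisfies all of them up to the recovery window's start.
* **Channel G's envelope** A(t) has no printed form; a raised-cosine
  window peaking at 15 mV inside 23–36 ks is used.

### Fluctuation process

Printed fluctuation amplitudes are "±x mV" **envelopes**.  They are
interpreted as a ~2-sd band: stationary sd = x/2.  The process is
band-limited Gaussian noise — white noise smoothed with a Gaussian kernel
of correlation time 3000 s (channel A: 5000 s), normalized so the
delivered sd is exact — and additionally saturated at the 2-sd envelope
(hard clip, rescaled; excursions never exceed ≈2.08 sd).  Two reasons:

1. Sampled extremes of white or Ornstein–Uhlenbeck noise grow with the
   number of samples (≈4.5 sd over a 450 k-sample recording), which would
   make the ensemble minimum drift far below the −90 mV dip and rob the
   printed ± envelopes of meaning.  A smooth process has a finite
   level-crossing rate, so extremes are controlled by the exposure time
   over the correlation length, not by the sampling rate.
2. The slow correlation time matches the described fluctuation periods
   (10³–10⁴ s) of these interfaces.

The envelope saturation makes the marginal slightly sub-Gaussian; the
delivered sd equals `noise_sd` exactly by construction.

Reproducibility: per-channel sub-seeds come from
`SeedSequence([master_seed, ord(label)])`, so single channels can be
re-simulated independently of the ensemble and identical (params, seed)
always give identical arrays.

Default sampling is dt = 0.4 s (2.5 Hz, the acquisition rate); analyses in
this repository typically run the full 180 ks span at dt = 4–8 s, which
preserves every model feature (the fastest deterministic structure is the
20 s spike kernel on channel A; all other time scales are ≥ 200 s).

## Digitization and Boolean logic

Each channel is binarized at its own **sample median** (strict `>` for
state 1; ties at the threshold go to 0).  For a continuous-valued trace
without ties this forces activation ratio 0.5 exactly (even n).
Transitions are counted between consecutive samples and the total time is
n·dt, under which the identity

    mean_high_duration = 2 · activation_ratio / transition_frequency

holds exactly for any stream that starts and ends low.

Gates are evaluated through their arithmetic identities on {0,1} (AND =
ab, OR = a+b−ab, XOR = a+b−2ab, their complements, AND3/OR3/MAJ/AND4); a
truth-table oracle cross-checks every identity exhaustively in the tests.
For inputs with marginals (p_A, p_B) and phi coefficient φ the expected
AND-output frequency is

    P(A∧B) = p_A p_B + φ·sqrt(p_A q_A p_B q_B),

clipped to the Fréchet bounds.  At (0.49, 0.49, φ=0) this gives 0.24; at
φ=−0.27 it gives 0.1726 ≈ 0.17 — the reconciliation between the
independence prediction and the measured anticorrelated output.  The
correlated-Bernoulli generator draws i.i.d. pairs from the exact 2×2 law
implied by (p_A, p_B, φ).

**Threshold robustness.** Shifting the per-channel thresholds by ±20%
(of the trace IQR, or of the threshold value) leaves the gates functional
on the default ensemble — outputs stay clear of the 0/1 rails and respond
monotonically — but does *not* bound the relative change of the output
frequency to a few percent.  That stronger robustness is a property of
rapidly switching recordings whose binary streams mix on time scales far
shorter than the recording; drift-dominated model traces concentrate
probability mass near the median, so their activation statistics are
intrinsically threshold-sensitive.  Passing tests here therefore do not
certify threshold robustness of real data.

## Spike statistics

The ISI workflow is: moving-median baseline removal (centered window;
window must exceed dt and fit in the trace), minimum-distance peak
extraction (greedy by height, ties to the earlier peak; default 1000
samples, the analysis convention, exposed as a parameter since the
appropriate value depends on the effective sampling rate), then

* CV = sample sd (ddof=1) / mean of the ISIs; CV = 1 characterizes a
  Poisson process, CV → 0 a metronome;
* a Kolmogorov–Smirnov test of the ISIs against Exp(λ̂), λ̂ = 1/mean ISI,
  with both one-sided ECDF jumps checked and the p-value from the
  Kolmogorov distribution using Stephens' small-sample scaling
  (√n + 0.12 + 0.11/√n)·D, which keeps the type-I error near nominal at
  n ≈ 100 (verified by a 1000-replicate calibration test with the rate
  known).  With λ estimated from the same data the test is
  anti-conservative (no Lilliefors correction is applied — the
  conventional procedure for this analysis);
* the Poisson-consistency verdict: p > α **and** |CV − 1| ≤ 0.2.  The CV
  band is needed because a metronomic train can pass the KS test on few
  events while being the opposite of Poisson; the band width 0.2 is a
  package choice, configurable.

## Impedance

The interface circuit is R₁ + (R₂ ∥ CPE) + Warburg:

    Z(ω) = R₁ + R₂/(1 + R₂Q(jω)ⁿ) + σω^(−1/2)(1 − j)

with the CPE interpolating between resistor (n=0) and ideal capacitor
(n=1) and the Warburg element fixed at −45°.  A multi-RC ladder is
provided for interface-stack modelling.  Fitting is complex nonlinear
least squares with modulus weighting, Σ[(ReΔ)² + (ImΔ)²]/|Z|², over
log₁₀(R₁, R₂, Q, σ) (positivity without constrained solvers) and bounded
n ∈ [0, 1]; reduced χ² uses 2N − 5 degrees of freedom.  That χ²
convention is a package choice — instrument software normalizes
differently, so χ² values are not comparable across tools.  Initialization
is automatic from the spectrum's asymptotes; non-convergence and
under-determined solutions (an element fitted to a vanishing contribution,
n pinned at a bound, or >100% parameter standard errors) are flagged, not
silently accepted.

Parameter recovery on synthetic spectra from the reference parameter set
(R₁=539.5 Ω, R₂=4.356 MΩ, Q=3.904 µS·sⁿ, n=0.940, σ=6332 Ω·s^(−1/2)):
better than 0.1% noiseless and better than 5% at 1% multiplicative noise
over 50 points spanning 0.01 Hz–100 kHz (10 seeds).

Series-equivalent conversions use the standard formulas (|Z|=√(R²+X²),
θ=atan2(X,R), C_s=−1/(2πfX) for X<0, D=R/|X|).  The printed 300 kHz LCR
readouts are mutually inconsistent under these formulas (e.g. computed
|Z| ≈ 6209 Ω vs printed 6043 Ω); the conversions are therefore exact
algebra on whatever readouts are supplied, and only the capacitance-ratio
arithmetic (+118%) is treated as reproducible.

## Morphometry

Pseudocolored (height-mapped) micrographs are segmented by hue after HSV
conversion: red-orange [0°, 60°) = elevated microspheres, yellow-green
[60°, 180°) = interfacial zones, cyan-blue [180°, 300°) = matrix.
Pixels with saturation or value below 0.1 are unassigned (hue is
meaningless near gray), as are hues in the unconfigured 300–360° band.
Area fractions are exact pixel counts; circular ROIs (electrode-centred)
reuse the same counting.  The pixel↔µm scale is a configuration input.

Box-counting fractal dimension: occupied-box counts over dyadic box sizes
from 2 px to min(shape)/4, least-squares slope of log N vs log(1/s), with
the fit R² reported so shallow or curved log-log relations are visible.
The estimator recovers 2.0 / 1.0 / 1.893 (±0.05) on filled-square /
line / depth-5 Sierpinski-carpet masks; on generated tri-region test
images the region-boundary dimension lands near 1.3–1.4.

## Synthetic fixtures

All generators are pure functions of (parameters, seed) on
`numpy.random.default_rng`.  Beyond those described above:

* **EIS spectra**: forward model times (1 + ε), ε complex Gaussian with
  per-component sd `rel_noise`.
* **Spike trains**: homogeneous Poisson (exponential ISIs), and a jittered
  lattice whose intervals are N(period, jitter_sd) — CV ≈ jitter_sd/period,
  emulating the metronomic low-CV regime.
* **Microsphere diameters**: a two-lognormal mixture, weights (0.60, 0.40)
  with medians ≈370 nm (σ_log=1.0) and ≈1990 nm (σ_log=0.33), calibrated
  numerically so a large sample has mean ≈1204 nm and sd ≈1072 nm while
  both populations (200–800 nm and 1500–2500 nm) hold ≥20% of the mass.
  No distribution family is claimed by the source data; lognormals are the
  standard positive-support choice for particle sizes.
* **Test images**: a smoothed random field thresholded at the requested
  pixel-count quantiles, giving irregular connected blobs with *exact*
  per-region areas, painted at hues 30°/120°/240° with gray elsewhere.

## What the synthetic data does not show

The generators emulate the *statistical structure the analyses assume* —
drift forms, envelopes, exact joint laws, known circuit parameters, known
area fractions — not the recordings themselves.  Quantities that depend on
the recordings' microstructure (fitted thresholds in mV, per-channel ISI
tables, measured fractal dimensions of real boundaries, threshold-
robustness percentages, the reported frequency–duration correlation of
−0.94, which direct computation on the printed summary rows does not
reproduce: r = −0.62) are deliberately not asserted as test targets.
Passing tests establish that the pipeline's mathematics is correct and
calibrated, and that it reproduces every quantity that is arithmetic on
printed values or a property of the stated models.

## Problem sizes

Tests and the acceptance script run the full 180 ks span at dt = 4–8 s
(22.5–45 k samples/channel), binary fixtures at n = 10⁵–10⁶, KS
calibration at 1000 replicates of n = 100, and images at 80–512 px —
sizes at which every asserted statistic is stable at the tolerance used.
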