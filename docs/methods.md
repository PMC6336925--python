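# Methods

## Overview

`fnirsfilt` is a parameter-recovery benchmark: synthetic multi-subject fNIRS
concentration data with a known task-evoked component are pushed through
configurable preprocessing (Beer–Lambert conversions, optional targeted-PCA
motion correction, a grid of digital filters) and a two-regressor GLM, and
every filter specification is scored by how well the group β-values recover
the known generating amplitude. This note documents the generative model,
the numerical choices, and what the benchmark's results do and do not say
about real data.

## Protocol and task component

The simulated experiment is a block design: `n_blocks` task blocks of
`task_dur` seconds alternating with `rest_dur` seconds of rest after a
`lead_in` rest. Defaults are 14 × (20 s + 20 s) with a 20 s lead-in — 580 s
at 5 Hz (2900 samples) and a stimulation frequency of
f_stim = 1/(20+20) = 0.025 Hz. The alignment of the boxcar inside the
record (the 20 s lead-in) is a package choice; it is configurable and only
affects edge behavior. Durations are converted to sample counts by
round-half-up.

The hemodynamic response function is a double gamma,
h(t) = Γ(t; a₁) − r·Γ(t; a₂) with unit-scale gamma densities and
undershoot weight r = 1/6. Rather than fixing textbook shape constants, the
two shapes are solved numerically so that the *analytic* extrema of h fall
exactly at `peak_time` (6 s) and `undershoot_time` (16 s); for the defaults
this gives a₁ ≈ 7.014, a₂ ≈ 15.339. The kernel starts at exactly zero, is
truncated at `kernel_duration` (32 s) and normalized to unit peak.

The task component is `amplitude × unit-peak(boxcar ⊛ h)`. Because the GLM
task regressor is the same unit-peak waveform, the generating amplitude
*is* the ground-truth β — on noise-free data OLS recovers it to machine
precision under all three serial-correlation treatments. Amplitude presets
(Molar): 0.8/−0.27 μM, 0.5/−0.17 μM, 0.3/−0.1 μM for ΔHbO₂/ΔHbR; the HbR
magnitude is ~1/3 of HbO₂, reflecting the weaker deoxyhemoglobin response.

## Resting-state noise model

Real resting recordings are emulated by four ingredients, all configurable
through `NoiseSpec` (concentrations in Molar; μM at the config boundary):

1. **Systemic oscillations** — sinusoids at cardiac (1.1 ± 0.15 Hz),
   respiratory (0.3 ± 0.05 Hz), Mayer-wave (0.095 ± 0.01 Hz) and
   very-low-frequency (0.02 ± 0.01 Hz) bands with default amplitudes 0.2,
   0.15, 0.2, 0.3 μM. Frequencies, amplitudes and phases are drawn once per
   subject and *shared across channels* (these processes are spatially
   global), with small per-channel perturbations (phase SD 0.5 rad,
   multiplicative amplitude SD 0.3). Sharing matters: if channels were
   independent, the 16-channel median would average physiological leakage
   away and group statistics would be unrealistically clean.
2. **A settling trend** — an exponential approach to plateau,
   −A·exp(−t/τ), with A ~ N(1.0, 0.5) μM and τ ~ N(180, 60) s per subject
   (HbO₂ rising toward baseline as perfusion and optode coupling stabilize
   after cap placement; HbR mirrored). Its direction is consistent across
   subjects, which is what makes inadequately filtered GLM fits
   systematically *overestimate* the response instead of merely scattering
   — the characteristic failure mode of low-order FIR and low-pass-only
   filtering.
3. **Channel drift** — a zero-mean smoothed random walk (RMS 0.5 μM,
   correlation time 120 s), independent per channel.
4. **White measurement noise** — 0.05 μM per sample.

The HbR channel shares the subject's systemic frequencies/amplitudes and
settling trend but draws independent phases, drift and white noise, and is
mirrored in sign and scaled by `hbr_scale` (default 1/3).

Per-subject and per-channel seeds derive deterministically from a single
master seed (`numpy.random.SeedSequence` spawning); a given configuration
and master seed reproduces the dataset bit for bit. The three amplitude
datasets share the same noise realizations — only the added task component
differs — matching a design in which different task amplitudes are
superimposed on the same resting recordings.

**What the generator does not model:** spatially structured (regional)
functional connectivity, wavelength-dependent noise at the intensity level,
heartbeat waveform harmonics, infant-specific spectra, non-stationary
oscillation amplitudes within a record, or task-correlated systemic
responses. A further known artifact: after sharp band-pass filtering the
surviving in-band leakage is dominated by one or two sinusoidal components,
so subject-median β distributions can look *non*-normal for good filters —
the opposite of what broadband real noise produces. Passing the benchmark
therefore validates the estimation machinery and the relative ordering of
filters under this noise structure, not absolute performance on any real
dataset.

## Beer–Lambert conversions

ΔOD_λ = (ε_HbO₂,λ·ΔHbO₂ + ε_HbR,λ·ΔHbR)·d·DPF with decadic extinction
coefficients, source–detector separation d = 3 cm and a single DPF of 6
applied at both wavelengths (705/830 nm). The packaged extinction table
holds standard compiled decadic molar values (1/(M·cm)); it is replaceable,
and every correctness property (round trip, linearity, commutation with LTI
filtering) is independent of the specific numbers. Log base 10 is paired
with decadic coefficients — conventions differ between toolboxes, so this
is stated explicitly.

## Motion correction

Detection flags any sample lying in a `t_motion` = 0.5 s window whose
excursion exceeds `std_thresh` = 10 × the channel noise scale or
`amp_thresh` = 5 (signal units); the noise scale is the SD of the channel's
first difference (robust to drift). Flags are dilated by `t_mask` = 1 s and
unioned over channels. Correction is targeted PCA: principal components of
the flagged-segment block (all channels jointly) are removed until the
cumulative explained variance reaches `n_sv` = 0.97, with re-detection up
to `max_iter` = 5 times. Samples outside the mask are never modified;
corrected segments are re-anchored by a linear ramp so their endpoints meet
the neighboring clean samples. These semantics follow the published
targeted-PCA description; internal details of the original Matlab
implementation (exact windowing and recursion bookkeeping) are approximated,
not asserted equivalent. Motion correction defaults to *off* in the sweep so
filter comparisons are not confounded by it.

## Filters

* **Butterworth (IIR)** — designed by bilinear transform in
  transfer-function (b, a) form and applied forward–backward (`filtfilt`,
  reflection padding of 3 × filter length). Zero phase; the magnitude
  response is squared, so the effective attenuation at f_c is −6 dB.
  Stability is judged on the (b, a) denominator roots in double precision
  with tolerance max |pole| < 1 − 1e−12; designs whose coefficients
  overflow to non-finite values are classified unstable. Stability is a
  property of this representation (a second-order-sections realization
  would behave differently); the transfer-function form is used throughout
  because that is how such filters are typically realized in practice and
  is what the benchmark's stability grid describes. Unstable designs are
  refused at application time and skipped in sweeps.
* **FIR** — Hamming-windowed linear-phase designs of length order+1
  (−6 dB at f_c, the `fir1`/`firwin` convention, vs −3 dB for IIR), applied
  in a single pass on a reflection-padded copy with the output advanced by
  the constant group delay (order/2 samples, rounded; odd orders retain a
  residual half-sample delay, below timing resolution of the block design).
* **Moving average** — uniform window scaled by 1/L, low-pass only. The
  cut-off → window mapping is L = round(0.443·fs/f_c), placing the first
  −3 dB point of the length-L average at f_c.

`amplitude_response` reports the *realized* magnitude (squared for
forward–backward IIR). The Kaiser FIR order estimate uses the standard
formula N ≈ (A − 7.95)/(2.285·Δω), rounded up to an even order. Welch PSDs
use 120 s symmetric-Hamming segments with 50% overlap, one-sided density
normalization.

The default sweep grid pairs {BW, FIR} × orders {3, 4, 5, 20, 100, 200,
500, 1000} with band-pass edges {0.01–0.09, 0.01–0.2, 0.01–0.3,
0.01–0.5} Hz and low-pass cut-offs {0.09, 0.1, 0.14, 0.5} Hz, plus
moving-average low-passes at {0.09, 0.1, 0.14} Hz.

## GLM and serial-correlation treatments

The design has two columns: the unit-peak task regressor and a constant.
β is the exact OLS solution; degrees of freedom n − 2. Three treatments:

* `none` — plain OLS on the filtered series.
* `downsample` — cubic-spline evaluation of both the data *and* the design
  columns on a 1 Hz grid before fitting (the regressor is rebuilt on the
  new grid by the same spline, so noise-free recovery stays exact). No
  extra anti-alias filter is applied: the filters under evaluation already
  band-limit the data below the new Nyquist frequency.
* `precolor` — data and design convolved with the HRF kernel normalized to
  unit sum (so the constant column survives), same-length with reflection
  padding and center-of-mass delay alignment. Precoloring does not whiten:
  it *imposes* a known smooth autocorrelation that dominates whatever the
  data brought, which is the property the unit tests assert (precolored
  residual lag-1 autocorrelation is high and insensitive to the intrinsic
  AR coefficient). Its practical benefit for point estimates is that the
  smoothed projection weights the passband where the filter response is
  flat, slightly reducing the attenuation bias of sharp filters.

Prewhitening (AR-IRLS) is out of scope; the benchmark compares only the
three treatments above.

## Group statistics and ranking

Channel βs are collapsed to a subject median over non-excluded channels;
group diagnostics are Shapiro–Wilk (valid for 3–50 subjects), Tukey fences
Q1 − 1.5·IQR / Q3 + 1.5·IQR with linear (type-7) quartiles, and a
two-sided one-sample t-test against the reference β (α = 0.05). Outliers
are reported, not removed (removal available behind a flag in the caller's
hands: the medians are exposed). Paired comparisons between pipelines use a
paired t-test; numerically identical pipelines (e.g. filtering ΔOD vs
concentration, which commute through the linear Beer–Lambert map) are
reported as a degenerate "no difference" instead of a meaningless t.

`rank_filters` orders specifications by mean |t| (default), |p − α|, or
mean absolute group bias, pooled over the chromophores/amplitudes/
corrections present in the table, with ties broken toward lower order and
then narrower passband. Ranking by |t| alone is kept as the default for
fidelity to the benchmark's framing, but it structurally rewards noisy
estimators (unremoved slow noise inflates the group SE faster than the
mean bias, deflating |t|, while a sharp filter's small deterministic
attenuation bias is measured precisely and so yields a large |t|); the
absolute-bias criterion does not suffer from this and is reported
alongside. Per-amplitude and pooled rankings are both available rather than
guessing a cross-amplitude weighting.

## Problem sizes

The shipped test suite runs the full pipeline at the study scale — 18
subjects × 16 channels × 580 s at 5 Hz — for the reduced-grid ordering
checks (one fixed master seed, plus ten seeds for the
precoloring-vs-no-correction average), and smaller configurations (2–4
subjects/channels) for mechanical checks. The full Table-style grid sweep
(~200 specifications) is a CLI run of a few minutes, not part of the test
suite.
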