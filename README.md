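# fnirsfilt

A simulation benchmark for choosing digital filters in functional
near-infrared spectroscopy (fNIRS) analyses.

## The problem

fNIRS measures task-evoked changes in oxy- and deoxyhemoglobin
concentration (ΔHbO₂, ΔHbR) optically, at sampling rates high enough to
capture cardiac (~1 Hz), respiratory (~0.3 Hz), Mayer-wave (~0.1 Hz) and
very-low-frequency (<0.04 Hz) physiological oscillations plus slow
instrumental drifts — all of which contaminate the hemodynamic response.
Practitioners disagree wildly about how to filter this data: band-pass vs
low-pass, Butterworth vs FIR vs moving average, and across a wide range of
orders and cut-offs. Because the true response in real data is unknown,
filter choices are hard to validate.

`fnirsfilt` takes the simulation route: it generates multi-subject,
multi-channel resting-state-like concentration data with realistic noise
structure, superimposes a *known* task component, runs the data through any
filter specification, and scores the filter by how well group-level GLM
β-estimates recover the known ground truth.

## The model

The task component is built by convolving a block-design boxcar (by default
14 blocks of 20 s task / 20 s rest, stimulation frequency
F_stim = 1/(20+20) = 0.025 Hz) with a canonical double-gamma hemodynamic
response function whose analytic peak is at 6 s and undershoot trough at
16 s. The component is normalized to unit peak and scaled by a preset
amplitude (e.g. 0.8 μM for ΔHbO₂, −0.27 μM for ΔHbR), so the generating
amplitude equals the β recoverable by ordinary least squares with the
matching unit-peak regressor:

    y = β·x_task + β₀·1 + ε,   β̂ = (XᵀX)⁻¹Xᵀy

Serial correlation is treated three ways: no correction, cubic-spline
down-sampling to 1 Hz, or precoloring (smoothing data and design with a
unit-sum HRF-shaped kernel). Channel βs are collapsed to subject medians;
group recovery is quantified by Shapiro–Wilk normality, Tukey-fence
outliers, and a one-sample t-test against the reference β (df = n−1).

Filters cover Butterworth IIR (applied forward–backward via `filtfilt`,
zero phase), linear-phase windowed FIR (single pass, group-delay
compensated) and moving averages, in band-pass and low-pass forms.
Butterworth stability is judged by transfer-function pole analysis in the
z-plane; high orders are unstable in this representation and those grid
cells are skipped, not force-stabilized. The modified Beer–Lambert law maps
between ΔOD and concentration; because it is linear and filters are LTI,
filtering in either domain yields the same β up to numerical tolerance.

## Worked example

```python
import numpy as np
from fnirsfilt import (AMPLITUDE_PRESETS, FilterSpec, HemodynamicGLM,
                       apply_filter, assemble_dataset, design_filter)

data = assemble_dataset(n_subjects=18, n_channels=16,
                        amplitudes=(AMPLITUDE_PRESETS[0],), master_seed=0)
spec = FilterSpec("BP", "FIR", 1000, fc_high=0.09, fc_low=0.01, fs=5.0)
coeffs = design_filter(spec)

betas = []
for rec in data["Amplitude1"]:
    mat = np.column_stack(
        [apply_filter(coeffs, hbo).values for hbo, _ in rec.channels])
    est = HemodynamicGLM(fs=5.0, correction="precolor").fit(mat)
    betas.append(np.median(est.beta_task_))
print(f"group mean beta = {np.mean(betas):.3e} M  (truth 8e-07 M)")
```

prints

```
group mean beta = 7.745e-07 M  (truth 8e-07 M)
```

i.e. the recommended sharp band-pass recovers the 0.8 μM ΔHbO₂ response to
within a few percent; the shortfall is the filter's removal of task energy
outside the passband, and wider or lower-order filters trade this for noise
leakage (run `fnirsfilt sweep` to compare a whole grid).

The command-line interface mirrors the library: `fnirsfilt simulate`
(write a dataset), `sweep` (grid → CSV of group statistics), `rank`
(order specifications by |t|, p-near-α, or absolute bias), `report`
(tables by order × cut-off plus the stability grid), `design` (one-off
stability/amplitude-response/Kaiser-order report).

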