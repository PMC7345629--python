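# Methods

## Scan model and geometry

The package models a monostatic circular scan in a single 2-D coronal
plane: one antenna transmits and receives at `M` equally spaced positions
on a circle of radius `trajectory_radius` around the rotation axis, and the
breast is a disc of radius `breast_radius` centred on that axis. All
coordinates are in metres, origin at the rotation axis, antenna 0 on the
+x axis, counter-clockwise indexing. Any consistent frame reproduces the
physics; this one makes rotation-symmetry tests trivial (rotating a target
layout by `2π/M` cyclically permutes the delay-tensor rows).

Propagation is modelled with a single average speed `v = c / sqrt(ε_avg)`.
`ε_avg` is the **area-weighted** mean permittivity over the disc bounded by
the antenna trajectory, `ε_avg = (ε_breast·A_breast + ε_bg·(A_scan −
A_breast)) / A_scan`. An average over per-path chords would be an equally
defensible reading of "average permittivity in the scan region"; the area
average was chosen as the simplest consistent estimator and is isolated
behind `estimate_propagation_speed` so it can be swapped without touching
anything else. Round-trip times of flight are straight-ray:
`t_m(r) = 2|r − r_m|/v`.

Default parameters:

| parameter | default | unit | rationale |
|---|---|---|---|
| `eps_breast` | 6.4 | – | adipose-mimicking material at the central scan frequency |
| `eps_bg` | 1.0 | – | system operates in air, no coupling medium |
| `trajectory_radius` | 0.15 | m | typical bench-top circular-scan chamber scale |
| `breast_radius` | 0.055 | m | mid-size breast phantom |
| `image_extent` | 0.15 | m | covers the breast disc with ~35% margin |
| frequency grid | 1–8 GHz × 1001 | Hz | stepped-frequency sweep of the clinical-scale system |
| time grid | 0–6 ns × 700 | s | ICZT output window of the clinical-scale system |
| `image_size` | 500 (clinical) / 100 (reduced) | px | presentation grid / desk-scale grid |

The trajectory radius, breast radius and image extent are not dictated by
the physics of the algorithms (all downstream metrics are ratio-based);
they only set the simulator's scene scale and the pixel pitch.

## Signal processing

S11 spectra are converted to the time domain by evaluating the inverse
transform `s_m(t_k) = (1/N_f) Σ_n S11[m,n] exp(+j 2π f_n t_k)` on the
configured uniform time grid. The fast path factors this through the
Bluestein chirp z-transform (`scipy.signal.czt`), exact to rounding; a
direct O(N²) evaluation is kept as `method="direct"` and as the oracle in
the tests. The `1/N_f` normalization and `+j` sign convention are
choices — a unit-amplitude scatterer yields an envelope peak near 1, and
every downstream metric is normalization-invariant.

Calibration is *ideal* reference subtraction: the target-free reference
scan is subtracted elementwise in the frequency domain before the
transform. Because both operations are linear they commute; the tests
assert this.

Beamforming operates on the **envelope** (pointwise modulus) of the complex
time signals. The multiplicative iterative update requires non-negative
data and images; signed or complex signals would violate that, so the
envelope is applied uniformly to DAS, DMAS, itDAS and itDMAS to keep the
four methods comparable. A coherent "complex" mode (coherent sums of the
real and imaginary parts, modulus at the end) is available for the
non-iterative beamformers via `reconstruct(..., signal_mode="complex")`
for sensitivity checks.

## Projectors and their pairing

The forward model discretizes the ideal impulse response by **nearest-bin
deposition**: pixel `i` adds `σ_i` to time bin `round(t_m(r_i)/Δt)` of
antenna `m`'s signal. The samplers in DAS/DMAS use the same nearest-bin
rule, which makes DAS the *exact matrix adjoint* of the forward projector —
the structural property the multiplicative update implicitly assumes, and
the central invariant of the test suite (`|⟨Fx,y⟩ − ⟨x,By⟩| ≤
1e-9·‖x‖‖y‖`). Linear-interpolation sampling is offered as an option but
breaks exact adjointness and is not the default. Delays outside the
recorded time window contribute zero on both sides (the only convention
that keeps the pair adjoint), and are excluded from the unity normalizers
consistently.

DMAS is computed through the identity `Σ_{m<n} a_m a_n = (S² − Q)/2`
(`S = Σ a_m`, `Q = Σ a_m²`), which is O(M) per pixel instead of O(M²); the
tests compare it against the explicit pair loop.

Images are stored **un-squared**; squaring is applied only at display and
metric time. The iterative update therefore operates on the linear
intensity map.

## Iterative update

```
I_0 = 1 (homogeneous),
I_{n+1} = ( I_n / B[U] ) ⊙ B[ (D ⊙ F[U]) / (F[I_n] + ε) ]
```

with `F[U]` the forward projection of the all-ones image (pixel counts per
time bin) and `B[U]` the back-projection of the all-ones sinogram (antenna
coverage per pixel; `M(M−1)/2` for DMAS at interior pixels). The typeset
grouping of the update admits more than one reading; this form — the data
multiplied by `F[U]`, the image ratio normalized by `B[U]` — follows the
MLEM ancestry and the flowchart description (forward-project the estimate,
ratio against the measured data, back-project, multiply). Its exact fixed
point at `I_0 = 1` is the all-ones dataset `D = U`: then `F[I_0] = F[U]`,
the ratio collapses to `D`, and `B[U]/B[U] = 1`.

Numerical guards, none of which the update's ancestry prescribes:

* `ε = 1e-12 · max(F[U])` added to the denominator (settable; `ε = 0`
  supported, with 0/0 bins contributing ratio 0, not 1);
* pixels with `B[U] = 0` (no antenna coverage) are frozen at 0;
* pixels outside the antenna circle are *not* masked by default.

The default stopping iteration is 6 — the balance of contrast and noise
adopted here; no automatic stopping rule is provided, and the full trace
(every image, every forward projection, the per-iteration max ratio) is
returned so callers can apply their own.

Cost accounting follows the model in which each projection costs `Ns`
signal summations (`Ns` = number of antenna signals): a run of `N`
iterations performs the two unity-normalizer initializations plus one
forward and one back projection per iteration, `2(N+1)` projections and
`2(N+1)·Ns` signal summations in total. The trace records these counts and
the tests assert them; wall-clock time is hardware-dependent and not
asserted anywhere.

For itDMAS the back-projection is simply swapped for DMAS. Because DMAS is
quadratic, the back-projected ratio is amplified quadratically; this is the
operator substitution as specified, documented rather than "corrected".

## Metrics

Evaluated on the squared intensity map. The tumor region is a disc of
radius `r_t + 5 mm` about the known tumor centre (the margin absorbs
placement uncertainty), intersected with the breast disc; clutter is breast
minus tumor region. `SMR = 20 log10(S_max/C_mean)`,
`SCR = 20 log10(S_max/C_max)`; identifiable ⇔ SCR > 0. The argmax for the
localization error is restricted to the breast mask (responses outside the
phantom are not clutter "belonging to the phantom"), ties broken toward the
smallest distance.

Uncertainty convention: σ(S_max) is the standard deviation (population,
ddof 0) of tumor-region pixels **at or above** the region's 75th-percentile
intensity, σ(C_max) likewise at the clutter 95th percentile, σ(C_mean) = 0;
percentiles are linearly interpolated. "Within the Nth percentile" is read
as the high-intensity tail — the pixels that determine the peaks whose
uncertainty is being estimated; the literal below-the-cutoff reading would
measure background noise instead, but is preserved behind the
`tail="lower"` option. The dB propagation is first-order:
`σ_SMR = (20/ln 10)·σ_S/S_max`, `σ_SCR` adds the clutter term in
quadrature. Note one algebraic subtlety pinned by the tests: squaring the
image exactly doubles SCR in dB (max commutes with squaring) but doubles
SMR only when the clutter is uniform, since the mean of squares is not the
squared mean.

## Synthetic scans

`simulate_scan` writes each point scatterer directly into the frequency
domain, `σ·exp(−j 2π f t_m(p))`, with complex Gaussian noise of modulus
std `noise_sigma` (components `N(0, σ/√2)`). The paired reference scan
carries an **independent** noise realization, so calibrated data carry
√2-inflated noise — matching the real two-scan protocol. Two reference
conventions are provided:

* `"tumor-free"` (default): the reference contains every scatterer except
  the tumor, so subtraction isolates the tumor plus noise — the cleanest
  setting for localization and linearity tests;
* `"adipose-only"`: the reference is empty, emulating the experimental
  protocol in which all inner tissue components are removed for the
  reference scan; clutter then survives calibration, which is what makes
  the density-class presets graded in difficulty.

The density presets (class I–IV) place 2/4/6/8 clutter scatterers of
relative amplitude 0.25/0.40/0.55/0.75 at seeded random positions inside
85% of the breast radius — an increasing-clutter proxy for the
fibroglandular-volume gradient across mammographic density classes.
Spherical scatterers (radius > 0) are rasterized as discs of uniformly
spaced point reflectors at the image pixel pitch sharing the total
reflectivity; point targets are the default.

The simulator deliberately shares the single-speed straight-ray delay model
with the reconstructor. This is an inverse crime by design: the synthetic
suite's job is algorithmic correctness (adjointness, fixed points, contrast
ordering, localization), not electromagnetic validation. Consequently,
passing tests demonstrate that the algorithms do what their equations say —
they do **not** demonstrate robustness to dispersion, attenuation,
multipath, skin reflections, antenna patterns or heterogeneous propagation
speed, none of which are modelled. The `eps_true` knob (simulate at a
permittivity different from the one the reconstruction assumes) probes
speed mismatch only.

## Problem sizes

The test suite and the acceptance script run at desk scale — 24 antenna
positions, 257 frequency points, 128 time bins, 100 × 100 pixels (1.5 mm
pixel pitch) — where the full four-method comparison takes well under a
second; the localization-recovery study uses 20 noisy scans. The
clinical-scale configuration (72 × 1001 × 700, 500²) is exercised through
its constructor and YAML fixture and is available for full-size runs.

## Known limitations

* The forward model carries no amplitude decay, antenna gain or path
  corrections (the operator accepts a per-position per-bin weight map as a
  hook for them).
* Reconstruction is 2-D in the antenna plane; no 3-D delay geometry.
* Lesion *size* is not estimated — contrast and localization metrics only.
* No DMAS-matched forward operator exists; itDMAS pairs the single
  radar forward model with DMAS back-projection,
  so the itDMAS pair is not adjoint and the quadratic back-projection can
  over-weight coherent structures.
* PNG export is visualization-only (8-bit, normalized); CSV/HDF5 round-trip
  losslessly.
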