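# bmiradar

Radar-based breast microwave image reconstruction: the DAS and DMAS
beamformers, their MLEM-style iterative counterparts (itDAS, itDMAS), the
full acquisition-to-image processing chain, contrast metrics, and a
synthetic monostatic-scan simulator.

## The problem

Breast microwave imaging (BMI) probes the breast with non-ionizing microwave
signals; the dielectric contrast between malignant and healthy tissue makes
tumors visible as strong reflectors. A monostatic radar system sweeps a
stepped-frequency signal (1–8 GHz) at antenna positions on a circle around
the breast and records the complex S11 reflection coefficient at each
position. Reconstruction turns this sinogram of radar signatures into a 2-D
reflectivity map.

The workhorse reconstruction is the **delay-and-sum (DAS)** beamformer,
which focuses the time-domain signals by summing each antenna's signal at
the round-trip time of flight of each pixel:

```
I(r) = Σ_m s_m(t_m(r)),        t_m(r) = 2 |r − r_m| / v
```

**DMAS** (delay-multiply-and-sum) rewards inter-antenna coherence by summing
pairwise products instead: `I(r) = Σ_{m<n} s_m(t_m(r)) · s_n(t_n(r))`.

The iterative methods embed these beamformers in the multiplicative update
of the MLEM algorithm from emission tomography. With a radar forward model
`F` (each pixel deposits its reflectivity at its time-of-flight bin,
`s_m(t) = Σ_i σ_i δ(t − t_m(r_i))`), back-projector `B` (DAS for itDAS, DMAS
for itDMAS), measured data `D` and unity normalizers:

```
I_{n+1} = ( I_n / B[U] ) ⊙ B[ (D ⊙ F[U]) / F[I_n] ]
```

starting from a homogeneous map and stopping at iteration 6. The
multiplicative structure rewards signal coherence while punishing
incoherence, suppressing both background and high-intensity clutter while
preserving the tumor response.

Image quality is scored on the squared intensity map by the
signal-to-mean ratio `SMR = 20 log10(S_max / C_mean)` and signal-to-clutter
ratio `SCR = 20 log10(S_max / C_max)`, where `S_max` is the peak response in
the known tumor region (tumor radius + 5 mm) and the clutter region is the
breast minus the tumor region. A reconstruction is *identifiable* iff
SCR > 0, i.e. the image maximum falls in the tumor region.

## Worked example

Simulate a phantom with one tumor (reflectivity 1.0) and two weaker clutter
reflectors, reconstruct with all four methods, and score the images:

```sh
bmiradar --seed 1 pipeline --fixture three-scatterer
```

```
 label    smr_db  smr_sigma_db   scr_db  scr_sigma_db  loc_err_mm  identifiable
   das 20.291786      0.076088 0.725288      1.431872    0.353553          True
  dmas 32.396177      0.150421 1.451996      1.849482    0.353553          True
 itdas 37.061226      0.144487 1.800996      2.174710    1.274755          True
itdmas 35.778005      0.247809 1.317329      2.327423    3.889087          True
```

Reading the table: every method localizes the tumor to within ~4 mm
(`loc_err_mm`) and places the image maximum inside the tumor region
(`identifiable`, SCR > 0). DMAS lifts the tumor-to-mean-clutter contrast by
~12 dB over DAS, and six multiplicative iterations (itDAS) add another
~5 dB on top of DMAS — the same ordering the iterative structure is designed
to produce: background clutter is progressively suppressed relative to the
coherent tumor response.

The same chain is available as a library:

```python
import bmiradar as br

cfg = br.ScanConfig.reduced()                    # 24 positions, 128 bins, 100²
fx = br.standard_fixtures(1)["three-scatterer"]
full, ref = br.simulate_scan(fx.phantom, cfg, noise_sigma=0.0, seed=fx.seed)
sino = br.to_time_domain(full, ref, cfg.time_grid)   # calibrate + ICZT + envelope
image = br.itdas(sino, cfg, n_iterations=6)
regions = br.MetricRegions.from_config(cfg, fx.phantom.tumor.position, 0.0)
print(br.evaluate(image, regions))
```

`ScanConfig.clinical()` gives the full-scale setup (72 positions, 1–8 GHz ×
1001 frequency points, 0–6 ns × 700 time points, 500 × 500 pixels);
`configs/clinical_72.yaml` and `configs/reduced_24.yaml` hold the same
configurations as YAML.

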