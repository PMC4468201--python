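# qdri

Quantitative diffuse reflectance imaging (QDRI) toolkit for wide-field
margin assessment with a 49-channel (7×7, 6 mm pitch) fiber-optic probe:

- **`qdri.optics`** — chromophore absorption (Beer–Lambert, bundled
  hemoglobin / β-carotene extinction compilations) and Mie-sphere reduced
  scattering; band averaging over the 450–600 nm analysis band.
- **`qdri.mc`** — forward Monte Carlo photon transport (hop–drop–spin,
  Henyey–Greenstein, Fresnel boundaries, Russian roulette) for homogeneous
  and layered media; single-baseline similarity scaling to arbitrary
  (μs′, μa); fiber-face collection with NA acceptance for the 8-around-1
  channel geometry (700 μm source–detector separation, 200 μm fibers,
  NA 0.22); inter-channel crosstalk simulation; reflectance lookup table.
- **`qdri.inversion`** — reference-measurement calibration (with
  self-calibration-channel drift removal) and bounded nonlinear
  least-squares spectral fitting to the scaled-MC forward model; 12-phantom
  leave-one-out cross-validation harness.
- **`qdri.scan`** — probe array parity (25 odd / 24 even checkerboard),
  raster planning (n² placements at 6/n mm), frame-to-map stitching,
  edge-kernel margin segmentation, SNR and RSD replicate statistics.
- **`qdri.landscape`** — [β-carotene]/⟨μs′⟩ ratio maps, empirical CDFs,
  two-sample Kolmogorov–Smirnov comparisons, breast-density strata.
- **`qdri.synthetic`** — the 12-phantom dilution series, Gaussian-random-
  field synthetic margins with class-dependent optical parameters, and raw
  frame synthesis (lamp shape, ≤2% source drift shared with the SC
  channels, shot noise).
- **`qdri.config` / `qdri.cli` / `qdri.io`** — YAML run configuration,
  plain-text frame/map formats, and the `qdri` command-line interface.

## CLI

```bash
qdri mc-baseline --mu-s 100 --g 0.9 --n-photons 400000 --seed 7 --out baseline.h5
qdri crosstalk --pitch 6 --mu-a 4.6 --mu-sp 6.9
qdri make-fixtures --out fixtures/
qdri scan-simulate --stratum HBD --n 8 --seed 0 --out scan/
qdri stitch --scan scan/ --param ratio --out map_ratio
qdri landscape --maps maps/ --out report/
qdri report --config run.yaml --out run_out/
```

Exit codes: 0 success, 2 config error, 3 data error, 4 numerical failure.

## Numerical notes

- "Semi-infinite" media are truncated at a configurable depth (default
  1.2 cm) and escape radius (3 cm); photons crossing are ledgered as
  transmitted/leaked. This is negligible for collection within 2 cm of the
  source and keeps zero-absorption runs bounded.
- Similarity scaling reweights a zero-absorption baseline by
  `exp(-mu_a * path)` and rescales exit radii by the interaction-coefficient
  ratio; it is validated (tests + acceptance) against independent direct
  simulations across the phantom property range, and warns outside the
  documented envelope.
- Energy is strictly ledgered: specular + diffuse + transmitted + absorbed
  + roulette-killed − roulette-boosted + leaked = launched, to float
  precision.
- The published SNR formula (`20·log10(mean/variance)`) is implemented
  verbatim; the conventional `mean/std` variant is available behind a flag.
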