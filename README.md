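# asymei

Simulation and retrieval toolkit for **asymmetric edge-illumination (EI)
x-ray phase-contrast imaging**. Synthetic phantoms (transmission,
refraction-angle and scattering-variance maps) are scanned through a
modelled two-mask/detector system to produce noisy per-column frame stacks
plus flat fields; the inverse pipeline flat-fields the frames, assembles the
four asymmetric subgroup images by shift-and-add, and inverts them with the
closed-form four-point algorithm into co-registered **absorption**,
**differential phase contrast (DPC)** and **dark-field** images. A
single-image phase-map mode for homogeneous objects is also provided.

## How it works

- **`asymei.ic_model`** — parametric illumination curve (Gaussian on a
  pedestal) with analytic first/second derivatives, and placement of the
  four asymmetric sampling points: the outer pair at 50% of the IC maximum,
  or directly from the mask subgroup shift pattern `{-s, 0, s, 2s}`
  (symmetrized by a global offset of `-s/2` to `{±s/2, ±3s/2}`).
- **`asymei.geometry`** — cone-beam magnification and pitch matching
  (100 µm detector pixels ↔ 75 µm / 97.5 µm mask pitches at 1.5 m / 1.95 m
  for a 2 m detector distance), refraction-angle → IC-displacement
  conversion, scan-step arithmetic.
- **`asymei.forward_sim`** — phantom rasterizer (slabs, wedges, cylinders,
  spheres with `n = 1 - δ + iβ` materials) and the scan simulator: each
  detector column belongs to one of four interleaved subgroups, sees the
  object at a per-column frame offset, and draws Poisson counts around the
  second-order IC expansion
  `I_j = I_R [R_j + Ṙ_j Δφ + ½R̈_j Δφ² + ½R̈_j σ²]`.
- **`asymei.retrieval`** — flat-fielding (mean of before/after flats,
  rescaled so vacuum = `R_j`), subgroup shift-and-add assembly (128 columns
  → 32 images per subgroup), the closed-form four-point inversion, and the
  linearized single-shot phase retrieval (exact exponential-integrator ODE
  solve along the scan direction).
- **`asymei.cli_io`** — strict YAML configuration, HDF5/TIFF round-tripping
  with config-hash + seed provenance, and the `asymei` CLI.

## CLI

```sh
asymei phantom  --config config.yaml --out phantom.h5
asymei simulate --config config.yaml --out frames.h5 [--seed N]
asymei retrieve --config config.yaml --frames frames.h5 --out outdir/ [--mode single_shot]
asymei demo     --out demo/        # end-to-end 3-material example + report.json
```

A minimal configuration (all keys optional, unknown keys rejected; units:
distances m, pitches/apertures/displacements µm, energies keV):

```yaml
geometry: {z_m1: 1.5, z_m2: 1.95, z_det: 2.0, detector_pitch: 100.0}
masks:
  m1: {pitch: 75.0, aperture: 21.4, subgroup_shifts: [-10.0, 0.0, 10.0, 20.0]}
  m2: {pitch: 97.5, aperture: 28.0}
phantom:
  grid: [24, 96]
  pixel_size: 75.0
  energy_keV: 80.0
  shapes:
    - {type: cylinder, cx: 3600.0, radius: 1200.0,
       material: {delta: 3.3e-8, beta: 1.5e-10, scatter: 0.0}}
acquisition: {flux: 100000.0, frame_rate: 32.0, speed: 2.4, n_columns: 128, seed: 7}
retrieval: {mode: multimodal, delta_beta: 220.0}
```

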