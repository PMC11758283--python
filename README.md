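# trsfx

Simulation and manifold-based recovery of time-resolved serial femtosecond
crystallography (TR-SFX) data.

The package implements a complete computational loop:

1. **Simulate** a time series of ground-truth diffraction volumes whose
   intensities evolve smoothly between two endmember states, then degrade
   it into realistic snapshot streams: per-snapshot random orientation,
   ~98% incompleteness from Ewald-sphere cuts, spot-sphere partiality,
   per-crystal scale factors, per-reflection Gaussian noise, and Gaussian
   timestamp jitter with out-of-range culling.
2. **Reconstruct** a complete, denoised, jitter-mitigated series of
   diffraction volumes with nonlinear Laplacian spectral analysis (NLSA):
   delay-coordinate embedding, a diffusion-map manifold basis, manifold
   projection, truncated SVD back-projection, and diagonal averaging.
3. **Benchmark** against Monte Carlo merging with per-time Pearson
   correlations and per-q-shell R-factors.

## Layout

| module              | contents                                              |
|---------------------|-------------------------------------------------------|
| `trsfx.core`        | unit cells, reciprocal geometry, Miller index sets, snapshot/volume types |
| `trsfx.simulate`    | dynamics specs, Ewald cuts, partiality, noise, jitter |
| `trsfx.preprocess`  | per-snapshot scale/Debye-Waller fits, standardization, densification |
| `trsfx.nlsa`        | delay embedding, diffusion maps, SVD modes, Hankelization |
| `trsfx.metrics`     | Monte Carlo merge, Pearson, q-shell R-factors, completeness |
| `trsfx.io` / `trsfx.cli` | text formats (snapshot stream, reflection lists, volume series) and the pipeline CLI |
| `trsfx.benchmarks`  | the desk-scale reference experiments used for acceptance |

## CLI

```sh
trsfx simulate --config run.cfg --out run/        # stream + truth + manifest
trsfx nlsa     --config run.cfg --stream run/snapshots.stream --out run/
trsfx merge    --stream run/snapshots.stream --out run/merged.hkl
trsfx metrics  --truth run/truth.volumes --recon run/reconstruction.volumes --out run/
trsfx all      --config run.cfg --out run/        # the whole chain
```

The config is a flat `key = value` file (unknown keys are rejected), e.g.

```ini
d_min = 7.6            # resolution cutoff (angstrom)
n_snapshots = 4096
spot_radius = auto     # calibrate to target_completeness (or 'rule', or a value)
target_completeness = 0.02
kappa = 1.0            # noise scale (x per-reflection std)
jitter_sigma = 0.0     # timestamp jitter (time units)
seed = 1
c = 256                # delay-embedding window
n_modes = 10           # SVD modes kept in the reconstruction
```

All randomness flows from one master seed through named substreams, so
reruns are byte-identical.

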