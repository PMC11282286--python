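# fiberdemix

Single-source activity demixing for short multimode-fiber (MMF) photometry.

Classical fiber photometry collapses the fluorescence of every labeled
neuron under an implanted fiber into one bulk trace. A *short* (~8 mm,
rigid) multimode fiber transmits each fluorescent source in its field of
view as a stable, source-specific intensity pattern — a **scattering
fingerprint** — at the proximal facet. A camera video of the superimposed
fingerprints is a nonnegative linear mixture

```
frame(t) = Σ_i  w_i · h_i(t) + noise
```

of fingerprint images `w_i` weighted by the calcium time traces `h_i(t)`.
Unconstrained non-negative matrix factorization (NMF) on the raw
pixels × frames matrix,

```
M ≈ W H,   W, H ≥ 0,   minimize ½‖M − W H‖²_F
```

(NNDSVD initialization, coordinate-descent solver, no regularization),
recovers both factors and restores single-source temporal resolution
without any fiber calibration. `fiberdemix` implements the full pipeline
for simulation studies and analysis of recorded TIFF videos:

- **synthetic data** — an LP-mode forward model of a step-index fiber
  (scaled to desk compute), a phenomenological fingerprint generator
  (ring/doublet/spiral/speckle geometry), sparse calcium and non-sparse
  neuropil traces, an optional scattering layer, and 8/16-bit camera
  digitization with shot/read noise and saturation tracking;
- **demixing** — NNDSVD + HALS coordinate descent (multiplicative updates
  as an internal oracle), optional pixel binning, and rank scanning that
  estimates the source count from the plateau of unique fingerprints;
- **evaluation** — GT–NMF and GT–GT Pearson correlation tables (ν, γ),
  greedy descending-correlation assignment, the diagonal summary
  δ_avg ± σ_δ, and the cross-talk summary ζ_avg ± σ_ζ from the
  off-diagonal absolute errors AE_ij = |ν_ij − γ_ij|;
- **I/O + CLI** — multi-page TIFF videos and components, CSV traces and
  tables, JSON configs with content hashes for bit-reproducible runs.

Intended users: groups building or evaluating fingerprint-photometry
probes, and anyone who wants a seeded, ground-truthed sandbox for NMF
demixing of fluorescence videos.

## Worked example

Simulate the six-bead scene (6 sparse calcium sources, one at the fiber
core edge; 1500 frames at 10 Hz; 16-bit camera with shot noise), demix with
rank 9, and evaluate the five best-recovered sources:

```sh
fiberdemix full-run --preset six_bead --seed 0 --frames 1500 \
    --rank 9 --subset 5 --out runs/six_bead
```

```
INFO NMF: rank=9 init=nndsvd solver=cd (cyclic HALS, W updated first) max_iter=3000 tol=0.0001
delta_avg = 99.7%
zeta_avg = 0.94%
```

`delta_avg` is the mean Pearson correlation between each of the five
best-matched ground-truth traces and its assigned NMF trace — 99.7% means
the traces are recovered nearly perfectly on this clean synthetic scene.
`zeta_avg` is the mean residual cross-talk: how much the off-diagonal
GT–NMF correlations deviate from the correlations the ground-truth traces
already have with each other; 0.94% means almost no activity leaked between
sources beyond that intrinsic overlap. The bundle under `runs/six_bead/`
contains the video and ground truth (`truth/`), the demixed components,
traces, correlation tables, side-by-side fingerprint panels and a hashed
manifest (`result/`).

The same pipeline is available as a library:

```python
from fiberdemix import NMFConfig, demix_video, evaluate_demix, generate_experiment

video, sources, config = generate_experiment("six_bead", seed=0, n_frames=1500)
result = demix_video(video, NMFConfig(rank=9))
report = evaluate_demix(sources, result, subset_size=5)
print(report.diagonal.delta_avg, report.crosstalk.zeta_avg)
```

Other presets: `dense_26_neuropil`, `dense_26_parafilm` (scattering layer),
`dominant_neuropil_21` (11 sources sharing one neuropil trace, 6× the
ensemble target signal), `ten_target_background`, `single_source_scan`.
Recorded videos can be analyzed directly with
`fiberdemix demix --video movie.tiff --rank 12 --out out/` and
`fiberdemix rank-scan --video movie.tiff --ranks 1:12 --out out/`.

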