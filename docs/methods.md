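# Methods

## Problem and model

Fiber photometry records bulk fluorescence through an implanted fiber and a
single detector, so the activity of individual neurons is lost in the
ensemble trace. A *short* (mm-scale, rigid) multimode fiber behaves
differently from the long fibers used in wavefront-shaping work: the
transmitted intensity pattern of a point source at the distal facet is not a
fully developed speckle but a structured, stable "scattering fingerprint"
that is unique to the source position. A camera video of the proximal facet
is then a nonnegative linear mixture

    frame(t) = Σ_i  w_i · h_i(t) + noise,

where `w_i` is the fingerprint image of source i and `h_i` its fluorescence
time trace. Factorizing the pixels × frames matrix of the raw video with
unconstrained non-negative matrix factorization (NMF),

    M ≈ W H,   W ≥ 0, H ≥ 0,   minimize ½‖M − WH‖²_F,

recovers the fingerprints (columns of W) and single-source traces (rows of
H) without any calibration of the fiber. This package implements that
pipeline end to end on synthetic data: fingerprint forward models, trace
and camera simulation, the NMF core, and the recovery statistics.

## Fingerprint forward models

**LP-mode model** (`fiberdemix.fiber`). In the weakly guiding approximation
a step-index fiber guides LP_lm modes; the solver finds every root of

    u J_{l+1}(u) K_l(w) = w K_{l+1}(w) J_l(u),   u² + w² = V²,

with V = 2πaNA/λ, by bracketing on a fine grid and polishing with Brent's
method. A point source at radial offset d excites each mode in proportion
to the mode amplitude at d; every mode accumulates its own phase βL over
the fiber length, and intensities are averaged incoherently over 11
wavelengths spanning a 30 nm emission band (fluorescence is incoherent;
11 samples empirically smooth the residual speckle). Off-axis sources
excite high-angular-momentum modes whose caustics form a bright ring whose
radius ρ grows with d; on-axis sources excite only l = 0 modes and give an
exactly cylindrically symmetric pattern. The real implantable fiber
(NA 0.39, 100 µm core radius; V ≈ 473, ~10⁴ modes) is far beyond desk
compute, so the default `SCALED_FIBER` uses a = 12.5 µm, NA 0.22 (V ≈ 33,
147 LP groups ≈ 270 modes with orientations); source positions stated in
real-fiber µm are rescaled by the core-radius ratio. This preserves the
ring/spiral morphology class, not the real fiber's mode statistics.

The ring-radius descriptor ρ is the argmax of the azimuthally averaged
radial intensity profile (subpixel circle sampling, lightly smoothed). It
is monotone in d across the core but *saturates* as the source approaches
the core edge, where the ideal-fiber ring dissolves into a plateau; the
monotonicity contract is therefore exercised on d ∈ [0, 0.9a] for the
physical model.

**Phenomenological model** (`fiberdemix.fingerprints`). Large synthetic
scenes use a constructive model of the same observed geometry: a ring at
ρ(d) (linear in d; a central blob at d = 0), a central bright doublet whose
alignment angle equals the source azimuth, spiral-arm modulation with
seeded arm count and phase, and — critically for demixing — a seeded
multiplicative log-normal speckle texture unique per source. Sources
beyond ~1.1 core radii are rolled off smoothly (sigmoid in d) to emulate
the low contrast of beads at the field-of-view border; beyond 1.2 core
radii the pattern is essentially dark and flagged out-of-FoV.

**Scattering layer.** A thin diffuser (e.g. a Parafilm film) between
sources and facet is modeled on the phenomenological path as a seeded
elastic warp (displacement field with Gaussian correlation length 5% of the
image), contrast reduction toward a diffuse pedestal (30% at strength 1),
and mild multiplicative speckle; on the physical path as a random phase
screen applied to the distal source field, coupled to the modes by grid
overlap integrals. Strength 0 is the identity; increasing strength strictly
lowers the azimuthal symmetry score (1/(1+relvar) of subpixel circle
samples) of an on-axis pattern.

## Traces and camera

Target (cell-body) traces are GECI-like: resting fluorescence F0 = 0,
instantaneous rise at each spike, single-exponential decay with τ = 1.0 s
at 10 Hz. Spike times are Bernoulli with 0.025/frame by default (~0.25
transients/s); per-source amplitudes are drawn from U(0.8, 1.2). The paper
trail for these statistics is thin, so they are plausible defaults exposed
in the run config rather than calibrated constants. Neuropil traces are
full-wave-rectified, 3-frame-smoothed Gaussian noise — nonnegative,
non-sparse (well over half of frames above 10% of max), fluctuating faster
than a calcium transient — scaled so the mean is 0.35 of a unit target
peak, which puts neuropil excursions on the order of target transients.

The camera applies gain (auto-scaled so the noiseless peak sits at half of
saturation when not set explicitly), Poisson shot noise on the count
expectation, Gaussian read noise (2 counts sCMOS preset, 1 count miniscope
preset), rounding, and clipping at 2^bits − 1 with a saturation mask.
Saturated pixels break the linearity NMF needs, so presets avoid them by
construction. The ensemble dynamic range is reported as max/min-positive of
the ensemble trace (one of several possible conventions; it is logged with
its definition).

## Presets

Presets mirror the bench scenes at desk scale (64×64 pixels, 10 Hz,
1500–2000 frames): `six_bead` (6 targets, one at the core edge),
`dense_26_neuropil` (25 targets, 3 near/past the border, 1 neuropil),
`dense_26_parafilm` (the same behind the scattering layer),
`dominant_neuropil_21` (10 targets + 11 sources sharing one neuropil trace,
rescaled so total neuropil is exactly 6× the time-averaged ensemble target
signal — which also puts it near 10× a single target's peak),
`ten_target_background` (10 targets + a diffuse global background whose
ensemble maximum is a configurable multiple, default 2.0, of the ensemble
activity maximum), and `single_source_scan` (one source stepped radially in
10 µm-equivalent steps, active in disjoint time blocks). All randomness
flows from one seed through named substreams (traces, noise, texture,
layer, positions), so runs are bit-reproducible and the noise seed can be
varied without touching the ground truth.

## NMF core

Initialization is plain NNDSVD: truncated SVD (randomized, fixed seed —
deterministic), leading triplet kept directly, subsequent singular pairs
split into positive/negative parts with the larger-energy part retained
and rescaled; zeros stay zeros. A "mean" fill variant exists because
multiplicative updates can never leave the zero set of the plain variant —
this is also why the cross-solver agreement check starts both solvers from
a shared random init.

The primary solver is cyclic coordinate descent (HALS): per outer
iteration, each column of W and then each row of H receives an exact
nonnegatively clipped least-squares update. The multiplicative-update
solver implements the classical Lee–Seung rules, whose loss is provably
non-increasing — it serves as an internal oracle, and scikit-learn's
coordinate-descent NMF (the tool the bench analysis itself used) serves as
an independent external check in the tests; both agree with the HALS
implementation to well under 1% in final loss. Iteration stops at
`max_iter` (default 3000) or when the relative loss decrease per iteration
falls below `tol` (default 1e-4; the method description fixes only
max_iter, so the tolerance is this package's addition and is logged when it
triggers). No regularization is applied: the demixing is deliberately
unconstrained, applied to raw counts with no preprocessing other than
optional pixel binning (block mean, scale preserving). After the fit,
spatial components are max-normalized with the scale folded into the
temporal components (reconstruction unchanged) and ordered by decreasing
temporal energy, ties broken by first-pixel index.

## Source counting by rank scanning

With rank above the true source count, the surplus components are replicas:
they either duplicate a fingerprint (high spatial correlation) or split one
fingerprint into spatially disjoint halves that share its singular time
trace (high temporal correlation). `rank_scan` therefore merges component
pairs exceeding 0.9 Pearson correlation in *either* view — spatial-only
merging was observed to miss splits entirely — drops components below 1% of
the strongest temporal energy, and reports the most frequent
unique-component count across the scanned ranks (ties toward the counts
seen at the largest ranks). Known limitation: under camera noise, ranks
just above the true count occasionally produce partial-mixture components
whose correlations fall in the 0.7–0.9 band; no fixed threshold separates
these from genuinely distinct sources, so counting is most reliable on
long, low-noise recordings (and the counting property is validated on
noiseless renders for 1–8 sources, plus a noisy 3-source case).

## Evaluation statistics

ν is the Pearson correlation table of GT traces against NMF traces, γ of GT
traces against themselves. Sources are assigned to components greedily in
descending order of ν (globally largest entry first, removed row and
column; ties to the lowest row/col index); an optimal assignment would
differ only in pathological near-tie cases and the greedy rule matches the
descending-correlation narrative of the bench analysis. The assigned
diagonal summarizes recovery (δ_avg, σ_δ); cross-talk beyond the intrinsic
GT–GT correlation is AE_ij = |ν_ij − γ_ij| over i ≠ j, summarized as ζ_avg
(plain mean) and σ_ζ. The alternative 1/(2(N_s−1)) prefactor sometimes
written for ζ_avg does not compute a mean for general subset sizes; it is
available (`printed_prefactor=True`) but the plain mean — which is what the
verbal definition describes — is the default. Standard deviations use the
population convention (divide by n), switchable. "First k beads" means the
k sources with the highest assigned correlation. Constant traces correlate
0 with a warning rather than NaN. All statistics are computed on fraction
scale; multiplying by 100 reproduces percent-scale reports exactly.

## What the synthetic twins do and do not show

The generator reproduces the *structure* of the bench experiments — source
counts, roles, neuropil dominance ratios, scattering, camera digitization,
shot noise — but its fingerprints are cleaner and more distinct than real
ones (ideal fiber, no bending, no focus drift, no motion, no photobleach,
exactly linear mixing). Recovery statistics on the twins are therefore
upper bounds on bench performance: passing the twin benchmarks shows the
pipeline implements the method correctly and meets the reported fidelity
under the stated conditions, not that it would reach the same numbers on
any real recording. Problem sizes were chosen as the package's desk-scale
defaults: 64×64 proximal images, 1500 frames (2000 for the dense scenes),
5 seeds per benchmark (10 for the background sweep).

## Numerical choices and degenerate inputs

- Mode solving caps V at 40 by default and raises with advice to scale the
  fiber down; dispersion roots are bracketed on a grid of ~40V points.
- Radial mode profiles are interpolated from 1500-point tables; mode fields
  are normalized by numerically integrated L2 norms.
- NMF HALS skips a component update when its Gram diagonal underflows;
  multiplicative updates guard denominators with machine epsilon.
- Loss is computed by the trace expansion ½(‖M‖² − 2⟨W, MHᵀ⟩ + ⟨WᵀW, HHᵀ⟩),
  avoiding a pixels × frames temporary.
- Pixel binning with a non-divisible factor crops trailing rows/columns and
  warns; binned stacks lose their integer bit depth (means are not counts).
- Empty evaluation subsets, single-source cross-talk subsets (no
  off-diagonal elements), NaN inputs and rank > min(shape) raise
  immediately with specific messages.
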