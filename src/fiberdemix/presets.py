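"""Seeded synthetic experiments emulating the bench proof-of-principle scenes.

Each preset builds a :class:`~fiberdemix.camera.SourceSet` (ground-truth
fingerprints, traces, positions, roles), renders it through a camera model,
and returns the video together with a fully serializable config record.
Presets mirror the bench experiments:

``six_bead``
    6 targets with sparse calcium traces; one bead sits at the core edge
    where its fingerprint has low signal (it is typically not recovered).
``dense_26_neuropil``
    25 targets (three near/beyond the field-of-view border) plus one
    neuropil source with a non-sparse trace.
``dense_26_parafilm``
    The dense scene with every fingerprint distorted by a thin scattering
    layer between the sources and the fiber facet.
``dominant_neuropil_21``
    10 targets plus 11 sources sharing one neuropil trace, rescaled so the
    total neuropil signal is ~6x the ensemble target signal (and ~10x each
    target's peak).
``ten_target_background``
    10 targets plus one diffuse global background whose ensemble maximum is
    ``background_ratio`` times the ensemble target maximum.
``single_source_scan``
    One source stepped radially in 10 µm-equivalent steps, active in
    disjoint time blocks (the fingerprint-geometry scan).

Positions are expressed in real-fiber µm (100 µm core radius) and mapped
onto the proximal image by the fingerprint model.
"""

from __future__ import annotations

import math
from typing import Any

import numpy as np

from ._rng import substream
from .camera import MINISCOPE, SCMOS, CameraModel, SourceSet, VideoStack, render_video
from .fiber import SourcePosition
from .fingerprints import REFERENCE_CORE_RADIUS, apply_scattering_layer, fingerprint_phenomenological
from .traces import TraceSpec, generate_calcium_trace, generate_neuropil_trace, poisson_spike_times

__all__ = ["generate_experiment", "PRESETS", "dynamic_range"]

PRESETS = (
    "six_bead",
    "dense_26_neuropil",
    "dense_26_parafilm",
    "dominant_neuropil_21",
    "ten_target_background",
    "single_source_scan",
)

_CAMERAS = {"sCMOS": SCMOS, "miniscope": MINISCOPE}

#: default per-frame spike probability at 10 Hz (~0.25 transients/s)
SPIKE_RATE = 0.025
#: neuropil mean amplitude relative to the unit target peak; abs-rectified
#: noise with this mean peaks near the target transient peak
NEUROPIL_RATIO = 0.35


def dynamic_range(trace: np.ndarray) -> float:
    """max / smallest positive value of an ensemble trace (one DR convention)."""
    trace = np.asarray(trace, dtype=float)
    pos = trace[trace > 0]
    if pos.size == 0:
        return 0.0
    return float(trace.max() / pos.min())


def _positions_on_rings(
    rng: np.random.Generator, radii: list[float], counts: list[int]
) -> list[SourcePosition]:
    """Beads on concentric rings with seeded radial/azimuthal jitter."""
    out = []
    for radius, count in zip(radii, counts):
        offset = rng.uniform(0, 2 * math.pi)
        for k in range(count):
            az = offset + 2 * math.pi * k / count + rng.normal(0, 0.08)
            d = max(radius + rng.normal(0, 4.0), 0.0)
            out.append(SourcePosition(d=d, azimuth=az % (2 * math.pi)))
    return out


def _target_trace(seed: int, index: int, n_frames: int, frame_rate: float) -> np.ndarray:
    rng = substream(seed, "traces", index)
    spikes = poisson_spike_times(n_frames, SPIKE_RATE, rng)
    if spikes.size == 0:  # a silent cell cannot be evaluated; force one event
        spikes = np.array([int(rng.integers(0, n_frames))])
    amp = float(rng.uniform(0.8, 1.2))
    spec = TraceSpec(
        kind="target",
        n_frames=n_frames,
        frame_rate=frame_rate,
        spike_times=spikes,
        decay_tau=1.0,
        amplitude=amp,
        seed=seed,
    )
    return generate_calcium_trace(spec)


def _neuropil_trace(seed: int, index: int, n_frames: int, frame_rate: float,
                    ratio: float = NEUROPIL_RATIO) -> np.ndarray:
    spec = TraceSpec(
        kind="neuropil",
        n_frames=n_frames,
        frame_rate=frame_rate,
        decay_tau=1.0,
        amplitude=1.0,
        seed=seed * 1009 + index,
    )
    return generate_neuropil_trace(spec, amplitude_ratio=ratio)


def _diffuse_background_image(image_size: int, seed: int) -> np.ndarray:
    """Broad, core-filling pattern for a global fluorescent background."""
    from scipy import ndimage

    n = image_size
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    r = np.hypot(x - c, y - c)
    core_px = 0.42 * n
    base = np.exp(-((r / (1.1 * core_px)) ** 4))
    g = ndimage.gaussian_filter(substream(seed, "texture", 999).standard_normal((n, n)), 4.0)
    g /= max(g.std(), 1e-12)
    base *= np.exp(0.25 * g)
    return base / base.max()


def _build_fingerprints(
    positions: list[SourcePosition],
    image_size: int,
    seed: int,
    scatter_strength: float,
) -> list:
    fps = [
        fingerprint_phenomenological(pos, image_size=image_size, texture_seed=seed, texture_index=i)
        for i, pos in enumerate(positions)
    ]
    if scatter_strength > 0:
        fps = [apply_scattering_layer(fp, layer_seed=seed, strength=scatter_strength) for fp in fps]
    return fps


def generate_experiment(
    preset: str,
    seed: int = 0,
    n_frames: int | None = None,
    image_size: int = 64,
    camera: str | CameraModel | None = "sCMOS",
    noise_seed: int | None = None,
    scatter_strength: float = 1.0,
    background_ratio: float = 2.0,
    neuropil_factor: float = 6.0,
) -> tuple[VideoStack, SourceSet, dict[str, Any]]:
    """Generate one synthetic experiment.

    Returns ``(video, sources, config)`` where config records every default
    actually used, so the run is reproducible bit-for-bit. ``camera`` is a
    preset name (``"sCMOS"``/``"miniscope"``), a :class:`CameraModel`, or
    None for the noiseless float video. ``scatter_strength`` only applies to
    the parafilm preset; ``background_ratio`` only to
    ``ten_target_background``; ``neuropil_factor`` (total neuropil /
    ensemble target signal) only to ``dominant_neuropil_21``.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {', '.join(PRESETS)}")
    if noise_seed is None:
        noise_seed = seed
    frame_rate = 10.0
    rng_pos = substream(seed, "positions")

    strength_used = 0.0
    extras: dict[str, Any] = {}

    if preset == "six_bead":
        n_frames = n_frames or 1500
        positions = _positions_on_rings(rng_pos, [15, 30, 45, 60, 75], [1] * 5)
        positions.append(SourcePosition(d=112.0, azimuth=float(rng_pos.uniform(0, 2 * math.pi))))
        roles = ["target"] * 6
        traces = [_target_trace(seed, i, n_frames, frame_rate) for i in range(6)]

    elif preset in ("dense_26_neuropil", "dense_26_parafilm"):
        n_frames = n_frames or 2000
        positions = _positions_on_rings(rng_pos, [25, 50, 75], [6, 8, 8])
        for d_edge in (105.0, 112.0, 118.0):
            positions.append(
                SourcePosition(d=d_edge, azimuth=float(rng_pos.uniform(0, 2 * math.pi)))
            )
        roles = ["target"] * 25
        traces = [_target_trace(seed, i, n_frames, frame_rate) for i in range(25)]
        positions.append(SourcePosition(d=40.0, azimuth=float(rng_pos.uniform(0, 2 * math.pi))))
        roles.append("neuropil")
        traces.append(_neuropil_trace(seed, 25, n_frames, frame_rate))
        if preset == "dense_26_parafilm":
            strength_used = scatter_strength

    elif preset == "dominant_neuropil_21":
        n_frames = n_frames or 1500
        positions = _positions_on_rings(rng_pos, [30, 60], [5, 5])
        roles = ["target"] * 10
        traces = [_target_trace(seed, i, n_frames, frame_rate) for i in range(10)]
        np_positions = _positions_on_rings(rng_pos, [20, 45, 70], [3, 4, 4])
        shared = _neuropil_trace(seed, 10, n_frames, frame_rate)
        positions += np_positions
        roles += ["neuropil"] * 11
        traces += [shared] * 11

    elif preset == "ten_target_background":
        n_frames = n_frames or 1500
        positions = _positions_on_rings(rng_pos, [30, 60], [5, 5])
        roles = ["target"] * 10
        traces = [_target_trace(seed, i, n_frames, frame_rate) for i in range(10)]
        positions.append(SourcePosition(d=0.0))
        roles.append("background")
        traces.append(_neuropil_trace(seed, 10, n_frames, frame_rate))

    elif preset == "single_source_scan":
        n_frames = n_frames or 1000
        steps = list(range(0, 100, 10))  # 10 µm-equivalent radial steps
        az = float(rng_pos.uniform(0, 2 * math.pi))
        positions = [SourcePosition(d=float(d), azimuth=az) for d in steps]
        roles = ["target"] * len(steps)
        block = n_frames // len(steps)
        traces = []
        for i in range(len(steps)):
            t = np.zeros(n_frames)
            t[i * block : (i + 1) * block] = _target_trace(seed, i, block, frame_rate)
            traces.append(t)
        extras["scan_steps_um"] = steps

    fingerprints = _build_fingerprints(positions, image_size, seed, strength_used)

    if preset == "ten_target_background":
        from .fiber import FingerprintPattern

        bg_img = _diffuse_background_image(image_size, seed)
        fingerprints[-1] = FingerprintPattern(
            image=bg_img, ring_radius=0.0, out_of_fov=False, position=positions[-1]
        )

    sources = SourceSet(
        fingerprints=fingerprints, traces=traces, positions=positions, roles=roles
    )

    # rescale shared/background traces to the prescribed signal ratios
    if preset == "dominant_neuropil_21":
        ratio = _signal_ratio(sources, role="neuropil")
        if ratio > 0:
            factor = neuropil_factor / ratio
            for i, role in enumerate(sources.roles):
                if role == "neuropil":
                    sources.traces[i] = sources.traces[i] * factor
            extras["neuropil_to_target_signal_ratio"] = neuropil_factor
            extras["neuropil_peak_over_target_peak"] = _peak_ratio(sources)
    elif preset == "ten_target_background":
        W = sources.fingerprint_stack().reshape(sources.n_sources, -1).sum(axis=1)
        H = sources.trace_matrix()
        tgt = sources.target_indices()
        act_max = (W[tgt, None] * H[tgt]).sum(axis=0).max()
        bg_max = (W[-1] * H[-1]).max()
        if bg_max > 0:
            sources.traces[-1] = sources.traces[-1] * (background_ratio * act_max / bg_max)
        extras["background_to_activity_max_ratio"] = background_ratio

    if isinstance(camera, str):
        if camera not in _CAMERAS:
            raise ValueError(f"unknown camera preset {camera!r}; available: {sorted(_CAMERAS)}")
        cam = _CAMERAS[camera]
    else:
        cam = camera
    video = render_video(sources, camera=cam, noise_seed=noise_seed)

    ensemble = video.frames.reshape(video.n_frames, -1).sum(axis=1).astype(float)
    gain_used = None
    if cam is not None and cam.gain is None:
        peak = sources.noiseless_video().max()
        gain_used = float(0.5 * cam.saturation_level / peak) if peak > 0 else 1.0

    config: dict[str, Any] = {
        "preset": preset,
        "seed": seed,
        "noise_seed": noise_seed,
        "n_frames": n_frames,
        "image_size": image_size,
        "frame_rate_hz": frame_rate,
        "camera": camera if isinstance(camera, str) else (None if camera is None else "custom"),
        "camera_gain_used": gain_used,
        "spike_rate_per_frame": SPIKE_RATE,
        "decay_tau_s": 1.0,
        "neuropil_amplitude_ratio": NEUROPIL_RATIO,
        "scatter_strength": strength_used,
        "core_radius_um": REFERENCE_CORE_RADIUS,
        "positions": [
            {"d_um": p.d, "azimuth_rad": p.azimuth, "diameter_um": p.diameter}
            for p in positions
        ],
        "roles": roles,
        "out_of_fov": [bool(fp.out_of_fov) for fp in sources.fingerprints],
        "dynamic_range": dynamic_range(ensemble),
        "dynamic_range_definition": "max(ensemble)/min positive ensemble value",
        **extras,
    }
    return video, sources, config


def _signal_ratio(sources: SourceSet, role: str) -> float:
    """Time-averaged total signal of ``role`` sources over target sources."""
    W = sources.fingerprint_stack().reshape(sources.n_sources, -1).sum(axis=1)
    H = sources.trace_matrix()
    sel = np.array([r == role for r in sources.roles])
    tgt = np.array([r == "target" for r in sources.roles])
    num = float((W[sel, None] * H[sel]).sum(axis=0).mean())
    den = float((W[tgt, None] * H[tgt]).sum(axis=0).mean())
    return num / den if den > 0 else 0.0


def _peak_ratio(sources: SourceSet) -> float:
    """Mean total neuropil signal over the mean per-target peak (video units)."""
    W = sources.fingerprint_stack().reshape(sources.n_sources, -1).sum(axis=1)
    H = sources.trace_matrix()
    sel = np.array([r == "neuropil" for r in sources.roles])
    tgt = [i for i, r in enumerate(sources.roles) if r == "target"]
    np_mean = float((W[sel, None] * H[sel]).sum(axis=0).mean())
    tgt_peaks = [float(W[i] * H[i].max()) for i in tgt]
    return np_mean / float(np.mean(tgt_peaks)) if tgt_peaks else 0.0
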