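"""Camera digitization model and video rendering.

The noiseless video is the exactly linear superposition
frame(t) = sum_i w_i * h_i(t) of fingerprint images weighted by their time
traces. A camera model then optionally applies Poisson shot noise, Gaussian
read noise, gain, integer quantization, and clipping at the saturation
level 2**bit_depth - 1 (saturated pixels are reported in a mask, since they
destroy the linearity NMF relies on).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._rng import substream
from .fiber import FingerprintPattern, SourcePosition

__all__ = ["CameraModel", "SourceSet", "VideoStack", "render_video", "SCMOS", "MINISCOPE"]


@dataclass(frozen=True)
class CameraModel:
    """Digitization parameters of the recording camera.

    ``gain`` converts intensity units to counts; ``gain=None`` auto-scales
    each rendered video so its noiseless peak sits at half the saturation
    level (logged in the run config). ``illumination_power`` is metadata
    (power transmitted through the fiber, µW).
    """

    bit_depth: int = 16
    gain: float | None = None
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    frame_rate: float = 10.0
    illumination_power: float = 9.5

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.gain is not None and self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be nonnegative")

    @property
    def saturation_level(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


#: bench-top scientific CMOS: deep wells, shot-noise limited
SCMOS = CameraModel(bit_depth=16, read_noise_sd=2.0, shot_noise=True, frame_rate=10.0)
#: head-mounted miniscope: shallow 8-bit digitization
MINISCOPE = CameraModel(bit_depth=8, read_noise_sd=1.0, shot_noise=True, frame_rate=10.0)


@dataclass
class SourceSet:
    """Ground truth of a scene: fingerprints w_i, traces h_i, positions, roles."""

    fingerprints: list[FingerprintPattern]
    traces: list[np.ndarray]
    positions: list[SourcePosition]
    roles: list[str]

    def __post_init__(self) -> None:
        n = len(self.fingerprints)
        if not (len(self.traces) == len(self.positions) == len(self.roles) == n):
            raise ValueError("fingerprints, traces, positions, roles must have equal length")
        self.traces = [np.asarray(t, dtype=float) for t in self.traces]
        lengths = {t.shape[0] for t in self.traces}
        if len(lengths) > 1:
            raise ValueError(f"all traces must share one length, got {sorted(lengths)}")
        shapes = {fp.image.shape for fp in self.fingerprints}
        if len(shapes) > 1:
            raise ValueError(f"all fingerprints must share one image size, got {sorted(shapes)}")
        for i, t in enumerate(self.traces):
            if np.any(t < 0):
                raise ValueError(f"trace {i} has negative values")
        for role in self.roles:
            if role not in ("target", "neuropil", "background"):
                raise ValueError(f"unknown role {role!r}")

    @property
    def n_sources(self) -> int:
        return len(self.fingerprints)

    @property
    def n_frames(self) -> int:
        return int(self.traces[0].shape[0]) if self.traces else 0

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.fingerprints[0].image.shape

    def target_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == "target"]

    def fingerprint_stack(self) -> np.ndarray:
        return np.stack([fp.image for fp in self.fingerprints])

    def trace_matrix(self) -> np.ndarray:
        """(n_sources, n_frames) matrix of ground-truth traces."""
        return np.stack(self.traces)

    def noiseless_video(self) -> np.ndarray:
        """(T, X, Y) float video: exactly linear in the sources."""
        W = self.fingerprint_stack()  # (N, X, Y)
        H = self.trace_matrix()  # (N, T)
        return np.tensordot(H.T, W, axes=(1, 0))


@dataclass
class VideoStack:
    """T frames of nonnegative camera counts plus camera metadata."""

    frames: np.ndarray  # (T, X, Y)
    bit_depth: int | None = None  # None for float (noiseless) stacks
    frame_rate: float = 10.0
    saturation_mask: np.ndarray | None = None  # (T, X, Y) bool

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, X, Y)")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("camera counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def saturation_level(self) -> int | None:
        return None if self.bit_depth is None else 2**self.bit_depth - 1

    def any_saturated(self) -> bool:
        return bool(self.saturation_mask is not None and self.saturation_mask.any())


def render_video(
    sources: SourceSet,
    camera: CameraModel | None = None,
    noise_seed: int = 0,
) -> VideoStack:
    """Render a source set into a video.

    With ``camera=None`` the exact noiseless float video is returned
    (sum_i w_i h_i(t), no quantization). With a camera model, gain is
    applied (auto-scaled if ``gain`` is None), then optional Poisson shot
    noise on the count expectation, Gaussian read noise, rounding to
    integers and clipping at the saturation level; pixels that reached
    saturation are flagged in ``saturation_mask``.
    """
    clean = sources.noiseless_video()
    if camera is None:
        return VideoStack(frames=clean, bit_depth=None, frame_rate=10.0)

    gain = camera.gain
    if gain is None:
        peak = clean.max()
        gain = (0.5 * camera.saturation_level / peak) if peak > 0 else 1.0
    expected = clean * gain

    rng = substream(noise_seed, "noise")
    if camera.shot_noise:
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected.copy()
    if camera.read_noise_sd > 0:
        counts += rng.normal(0.0, camera.read_noise_sd, size=counts.shape)
    counts = np.rint(counts)
    counts = np.clip(counts, 0, camera.saturation_level)
    mask = counts >= camera.saturation_level
    return VideoStack(
        frames=counts.astype(camera.dtype),
        bit_depth=camera.bit_depth,
        frame_rate=camera.frame_rate,
        saturation_mask=mask,
    )
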