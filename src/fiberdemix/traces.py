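"""Ground-truth time traces: sparse calcium transients and neuropil noise.

Target sources carry GECI-like traces: zero resting fluorescence (F0 = 0),
instantaneous rise at each spike and single-exponential decay. Neuropil
sources carry a rapidly fluctuating, non-sparse, nonnegative trace shared
by all neuropil sources in a scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream

__all__ = [
    "TraceSpec",
    "generate_calcium_trace",
    "generate_neuropil_trace",
    "poisson_spike_times",
]


@dataclass
class TraceSpec:
    """Parameters of one ground-truth trace.

    ``decay_tau`` is in seconds; ``spike_times`` are frame indices and apply
    to target traces only. ``amplitude`` sets the per-spike jump (target) or
    the scale of the fluctuating signal (neuropil), in arbitrary
    fluorescence units. ``baseline_F0`` defaults to 0: resting fluorescence
    is not modeled.
    """

    kind: str = "target"
    n_frames: int = 1500
    frame_rate: float = 10.0
    spike_times: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    decay_tau: float = 1.0
    amplitude: float = 1.0
    baseline_F0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("target", "neuropil"):
            raise ValueError("kind must be 'target' or 'neuropil'")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.baseline_F0 < 0:
            raise ValueError("baseline_F0 must be nonnegative")
        self.spike_times = np.asarray(self.spike_times, dtype=int)
        if self.spike_times.size and (
            self.spike_times.min() < 0 or self.spike_times.max() >= self.n_frames
        ):
            raise ValueError("spike_times must lie in [0, n_frames)")


def generate_calcium_trace(spec: TraceSpec) -> np.ndarray:
    """Sparse calcium-transient trace: sum of one-sided exponential kernels.

    trace(t) = F0 + sum_s A * exp(-(t - t_s)/tau) for t >= t_s, with an
    instantaneous rise at each spike frame. Linear in the spike set.
    """
    if spec.kind != "target":
        raise ValueError("generate_calcium_trace expects a target TraceSpec")
    if spec.decay_tau <= 0:
        raise ValueError("decay_tau must be positive")
    t = np.arange(spec.n_frames, dtype=float)
    tau_frames = spec.decay_tau * spec.frame_rate
    trace = np.full(spec.n_frames, float(spec.baseline_F0))
    for ts in spec.spike_times:
        dt = t - ts
        trace += np.where(dt >= 0, spec.amplitude * np.exp(-np.maximum(dt, 0) / tau_frames), 0.0)
    return trace


def generate_neuropil_trace(spec: TraceSpec, amplitude_ratio: float = 1.0) -> np.ndarray:
    """Non-sparse neuropil-like trace: rectified low-pass Gaussian noise.

    Seeded white noise is smoothed over ~3 frames (fluctuations faster than
    the calcium decay) and full-wave rectified, giving a nonnegative trace
    active in most frames (well over half the frames exceed 10% of the
    maximum). Scaled so its mean is ``amplitude_ratio * spec.amplitude``,
    i.e. comparable to a target's peak when the ratio is 1.
    """
    if spec.kind != "neuropil":
        raise ValueError("generate_neuropil_trace expects a neuropil TraceSpec")
    if amplitude_ratio < 0:
        raise ValueError("amplitude_ratio must be nonnegative")
    if amplitude_ratio == 0:
        return np.zeros(spec.n_frames)
    rng = substream(spec.seed, "traces")
    g = rng.standard_normal(spec.n_frames)
    # moving-average over 3 frames: faster than the ~tau*rate frames of a transient
    kernel = np.ones(3) / 3.0
    g = np.convolve(g, kernel, mode="same")
    trace = np.abs(g)
    mean = trace.mean()
    if mean > 0:
        trace *= amplitude_ratio * spec.amplitude / mean
    return trace + spec.baseline_F0


def poisson_spike_times(
    n_frames: int, rate_per_frame: float, rng: np.random.Generator
) -> np.ndarray:
    """Frame indices of a Bernoulli (discretized Poisson) spike train."""
    if rate_per_frame < 0:
        raise ValueError("rate must be nonnegative")
    return np.nonzero(rng.random(n_frames) < rate_per_frame)[0]
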