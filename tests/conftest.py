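import numpy as np
import pytest

from fiberdemix.camera import SCMOS, SourceSet, render_video
from fiberdemix.fiber import SourcePosition
from fiberdemix.fingerprints import fingerprint_phenomenological
from fiberdemix.traces import TraceSpec, generate_calcium_trace


def make_sources(n_sources: int, n_frames: int = 400, image_size: int = 48,
                 seed: int = 0) -> SourceSet:
    """Small scene with well-separated sources and sparse traces."""
    rng = np.random.default_rng(seed)
    positions, fingerprints, traces = [], [], []
    for i in range(n_sources):
        d = 10.0 + 80.0 * i / max(n_sources - 1, 1) * 0.9
        az = 2 * np.pi * i / max(n_sources, 1) + rng.uniform(0, 0.3)
        pos = SourcePosition(d=d, azimuth=az)
        positions.append(pos)
        fingerprints.append(
            fingerprint_phenomenological(pos, image_size=image_size,
                                         texture_seed=seed, texture_index=i)
        )
        spikes = np.sort(rng.choice(n_frames, size=max(4, n_frames // 40), replace=False))
        traces.append(generate_calcium_trace(TraceSpec(
            kind="target", n_frames=n_frames, frame_rate=10.0,
            spike_times=spikes, decay_tau=1.0,
            amplitude=float(rng.uniform(0.8, 1.2)),
        )))
    return SourceSet(fingerprints=fingerprints, traces=traces,
                     positions=positions, roles=["target"] * n_sources)


@pytest.fixture(scope="session")
def three_source_scene():
    return make_sources(3)


@pytest.fixture(scope="session")
def three_source_video(three_source_scene):
    return render_video(three_source_scene, SCMOS, noise_seed=7)
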