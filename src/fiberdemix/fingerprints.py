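"""Phenomenological scattering-fingerprint generator and scattering layer.

The LP-mode forward model (:mod:`fiberdemix.fiber`) reproduces fingerprint
morphology from first principles but is tied to a scaled fiber. For building
large synthetic experiments a phenomenological model is used instead: it
composes the empirically observed geometry of short-fiber fingerprints —
a bright ring whose radius grows with the source offset d, a central bright
doublet aligned with the source azimuth, spiral-arm ramifications, and a
per-source speckle texture — into a deterministic, seeded intensity image.
The speckle texture is what makes each source's fingerprint unique, which is
the property NMF demixing relies on.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from ._rng import substream
from .fiber import (
    FOV_CUTOFF,
    FOV_MARGIN,
    FingerprintPattern,
    SourcePosition,
)

__all__ = ["fingerprint_phenomenological", "apply_scattering_layer"]

#: real-fiber core radius (µm) to which source positions refer
REFERENCE_CORE_RADIUS = 100.0


def _fov_attenuation(d: float, core_radius: float) -> float:
    """Smooth roll-off for sources at or beyond the core edge.

    Emulates the low signal/contrast of beads near the field-of-view border;
    ~1 inside the core, ~0.5 at 1.1 a, near zero beyond 1.2 a.
    """
    edge = FOV_MARGIN * core_radius
    width = 0.04 * core_radius
    return float(1.0 / (1.0 + math.exp((d - edge) / width)))


def fingerprint_phenomenological(
    pos: SourcePosition,
    image_size: int = 64,
    texture_seed: int = 0,
    texture_index: int = 0,
    core_radius: float = REFERENCE_CORE_RADIUS,
    speckle_contrast: float = 0.9,
    spiral_contrast: float = 0.35,
) -> FingerprintPattern:
    """Seeded synthetic fingerprint for a source at ``pos``.

    The image is a product/sum of:

    * a ring at radius ``rho(d)``, where rho maps ``d`` linearly onto the
      proximal core image (rho(0) = 0: a central blob, no ring);
    * a central bright doublet whose separation grows with ``d`` and whose
      alignment angle equals the source azimuth;
    * multiplicative spiral-arm modulation (seeded phase and arm count);
    * multiplicative log-normal speckle (gaussian random field, smoothed,
      exponentiated) unique to ``texture_seed``;
    * a smooth envelope confining light to the core image, and an
      out-of-field-of-view roll-off for d beyond ~1.1 core radii.

    Deterministic in ``(pos, image_size, texture_seed)``; all pixels >= 0.
    """
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    rng = substream(texture_seed, "texture", texture_index)

    n = image_size
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    r = np.hypot(x - c, y - c)
    th = np.arctan2(y - c, x - c)

    core_px = 0.42 * n  # core radius on the proximal image, pixels
    rho = core_px * min(pos.d / core_radius, FOV_CUTOFF)  # monotone map of d
    sigma_ring = 0.10 * core_px

    if rho < 1.0:
        base = np.exp(-(r**2) / (2 * (0.22 * core_px) ** 2))
        ring_radius = 0.0
    else:
        base = np.exp(-((r - rho) ** 2) / (2 * sigma_ring**2))
        # faint interior plateau: light scattered inside the ring
        base += 0.25 * np.exp(-(r**2) / (2 * (0.8 * rho) ** 2))
        ring_radius = rho

    # central doublet aligned with the source azimuth
    sep = 0.12 * core_px * min(pos.d / core_radius, 1.0)
    if sep > 0.5:
        sig_d = 0.05 * core_px
        for sgn in (1.0, -1.0):
            px = c + sgn * sep * math.cos(pos.azimuth)
            py = c + sgn * sep * math.sin(pos.azimuth)
            base += 0.6 * np.exp(-(((x - px) ** 2 + (y - py) ** 2) / (2 * sig_d**2)))

    # spiral-arm modulation, seeded
    n_arms = int(rng.integers(2, 5))
    phase = float(rng.uniform(0, 2 * math.pi))
    twist = float(rng.uniform(0.15, 0.35)) * (2 * math.pi / max(core_px, 1.0))
    spiral = 1.0 + spiral_contrast * np.cos(n_arms * (th - pos.azimuth) + twist * r * n_arms + phase)
    base *= spiral

    # seeded multiplicative speckle texture (log-normal)
    if speckle_contrast > 0:
        g = rng.standard_normal((n, n))
        g = ndimage.gaussian_filter(g, 1.5)
        g /= max(g.std(), 1e-12)
        base *= np.exp(speckle_contrast * g)

    # confine to the core image and roll off out-of-FoV sources
    envelope = np.exp(-((r / (1.15 * core_px)) ** 6))
    base *= envelope
    atten = _fov_attenuation(pos.d, core_radius)
    base *= atten

    peak = base.max()
    if peak > 0:
        base = base / peak * max(atten, 0.0)
    oof = pos.out_of_fov(core_radius)
    if pos.d > FOV_CUTOFF * core_radius:
        base *= 1e-3  # essentially dark: outside the collection FoV

    return FingerprintPattern(
        image=np.maximum(base, 0.0),
        ring_radius=ring_radius,
        out_of_fov=oof,
        position=pos,
    )


def apply_scattering_layer(
    pattern: FingerprintPattern | np.ndarray,
    layer_seed: int = 0,
    strength: float = 1.0,
) -> FingerprintPattern:
    """Distort a fingerprint as a thin scattering layer (e.g. Parafilm) would.

    Phenomenological path: a seeded random elastic warp (displacement field
    with gaussian correlation length 5% of the image), contrast reduction
    toward a diffuse pedestal, and mild multiplicative speckle. At strength
    0 the input is returned unchanged; increasing strength strictly lowers
    the azimuthal symmetry score of an on-axis source's pattern.

    Deterministic in ``layer_seed``.
    """
    if strength < 0:
        raise ValueError("strength must be nonnegative")
    if isinstance(pattern, FingerprintPattern):
        img = pattern.image
        pos = pattern.position
        oof = pattern.out_of_fov
    else:
        img = np.asarray(pattern, dtype=float)
        pos = None
        oof = False
    if strength == 0:
        return FingerprintPattern(
            image=img.copy(),
            ring_radius=float(getattr(pattern, "ring_radius", 0.0)),
            out_of_fov=oof,
            position=pos,
        )

    rng = substream(layer_seed, "layer")
    n = img.shape[0]
    corr_len = 0.05 * n  # gaussian correlation length: 5% of the core image

    # random displacement field, correlated over corr_len
    disp = rng.standard_normal((2, *img.shape))
    disp = ndimage.gaussian_filter(disp, (0, corr_len, corr_len))
    for k in range(2):
        disp[k] /= max(np.abs(disp[k]).max(), 1e-12)
    amplitude = strength * 0.06 * n
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
    warped = ndimage.map_coordinates(
        img,
        [yy + amplitude * disp[0], xx + amplitude * disp[1]],
        order=1,
        mode="nearest",
    )

    # contrast reduction toward a diffuse pedestal
    mix = min(0.3 * strength, 0.9)
    pedestal = ndimage.gaussian_filter(warped, 0.15 * n)
    out = (1.0 - mix) * warped + mix * pedestal

    # residual speckle noise imprinted by the layer
    g = ndimage.gaussian_filter(rng.standard_normal(img.shape), 1.0)
    g /= max(g.std(), 1e-12)
    out = out * np.exp(min(0.2 * strength, 1.0) * g)

    out = np.maximum(out, 0.0)
    from .fiber import ring_radius_of

    return FingerprintPattern(
        image=out,
        ring_radius=ring_radius_of(out),
        out_of_fov=oof,
        position=pos,
    )
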