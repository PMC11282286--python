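"""Step-index multimode fiber forward model.

A short (mm-scale) step-index fiber transmits the fluorescence of a point
source at its distal facet as a structured intensity pattern — a
"scattering fingerprint" — at the proximal facet. In the weakly guiding
approximation the guided field decomposes onto LP_lm modes; each mode picks
up its own propagation phase exp(i beta_lm L) over the fiber length, and the
proximal intensity is the incoherent (wavelength-averaged) superposition of
the resulting interference patterns. Off-axis sources excite high-angular-
momentum modes whose caustics form a bright ring whose radius grows with the
source's radial offset d.

The real implantable fiber (NA 0.39, 200 µm core) guides ~10^4 modes and is
intractable on a desktop; the default simulation uses a proportionally
scaled fiber (V ≈ 33, a few hundred modes) that preserves the ring/spiral
morphology class. Source positions are expressed in real-fiber µm and
rescaled internally.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.optimize import brentq

__all__ = [
    "FiberSpec",
    "SourcePosition",
    "FingerprintPattern",
    "LPMode",
    "solve_lp_modes",
    "fingerprint_physical",
    "fiber_geometry_summary",
    "ring_radius_of",
    "azimuthal_mean_profile",
    "azimuthal_symmetry_score",
    "SCALED_FIBER",
    "REAL_FIBER",
]

#: sources beyond this multiple of the core radius are flagged out-of-FoV
FOV_MARGIN = 1.1
#: beyond this multiple the pattern is essentially zero
FOV_CUTOFF = 1.2

#: guided-mode count grows ~V^2/4; above this ceiling the solve is refused
DEFAULT_V_CEILING = 40.0


@dataclass(frozen=True)
class FiberSpec:
    """Geometry and optics of a step-index multimode fiber.

    Parameters
    ----------
    numerical_aperture : float
        NA = sqrt(n_core^2 - n_clad^2), in (0, 1).
    core_radius : float
        Core radius *a* in µm.
    length : float
        Fiber length in mm.
    center_wavelength : float
        Center of the fluorescence emission band, µm.
    bandwidth : float
        Full width of the emission band, µm (0 = monochromatic).
    refractive_index_core : float
        Core index n1.
    """

    numerical_aperture: float = 0.22
    core_radius: float = 12.5
    length: float = 8.0
    center_wavelength: float = 0.518
    bandwidth: float = 0.030
    refractive_index_core: float = 1.46

    def __post_init__(self) -> None:
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError("numerical_aperture must be in (0, 1)")
        if self.core_radius <= 0:
            raise ValueError("core_radius must be positive")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be nonnegative")
        if self.refractive_index_core <= self.numerical_aperture:
            raise ValueError("core index must exceed the NA")

    @property
    def n_clad(self) -> float:
        return math.sqrt(self.refractive_index_core**2 - self.numerical_aperture**2)

    def v_number(self, wavelength: float | None = None) -> float:
        """Normalized frequency V = 2*pi*a*NA/lambda."""
        lam = self.center_wavelength if wavelength is None else wavelength
        if lam <= 0:
            raise ValueError("wavelength must be positive")
        return 2.0 * math.pi * self.core_radius * self.numerical_aperture / lam

    def wavelength_samples(self, n: int) -> np.ndarray:
        """``n`` equally spaced wavelengths across the emission band."""
        if n < 1:
            raise ValueError("need at least one wavelength sample")
        if n == 1 or self.bandwidth == 0:
            return np.array([self.center_wavelength])
        half = self.bandwidth / 2.0
        return np.linspace(self.center_wavelength - half, self.center_wavelength + half, n)


#: desk-scale stand-in for the real fiber (V ≈ 33, ~270 modes)
SCALED_FIBER = FiberSpec(numerical_aperture=0.22, core_radius=12.5)
#: the physical fiber of the bench experiments (V ≈ 473 — not solvable here)
REAL_FIBER = FiberSpec(numerical_aperture=0.39, core_radius=100.0)


@dataclass(frozen=True)
class SourcePosition:
    """Position of a fluorescent point source at the distal facet.

    ``d`` is the radial offset from the fiber axis and ``azimuth`` the angle
    (counterclockwise from +x), both in the real fiber's coordinates (µm);
    positions are rescaled when a scaled fiber is simulated.
    """

    d: float
    azimuth: float = 0.0
    diameter: float = 10.0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("radial offset d must be nonnegative")
        if self.diameter <= 0:
            raise ValueError("source diameter must be positive")

    def out_of_fov(self, core_radius: float, margin: float = FOV_MARGIN) -> bool:
        return self.d > margin * core_radius


@dataclass
class FingerprintPattern:
    """A proximal-facet intensity map for a single source.

    ``ring_radius`` is the intensity-weighted mean radius of the pattern in
    pixels — the descriptor rho of the bright ring, which grows with the
    source offset d.
    """

    image: np.ndarray
    ring_radius: float = 0.0
    out_of_fov: bool = False
    position: SourcePosition | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("fingerprint image must be 2D")
        if np.any(self.image < 0):
            raise ValueError("fingerprint intensities must be nonnegative")
        if self.ring_radius < 0:
            raise ValueError("ring_radius must be nonnegative")


@dataclass(frozen=True)
class LPMode:
    """One guided LP_lm mode of a step-index fiber."""

    l: int  # azimuthal order
    m: int  # radial order (1-based)
    u: float  # transverse core parameter
    w: float  # cladding decay parameter
    b: float  # normalized propagation parameter in (0, 1)
    beta: float  # propagation constant, rad/µm

    def radial_profile(self, r: np.ndarray, core_radius: float) -> np.ndarray:
        """Normalized transverse profile R(r); continuous at the core edge."""
        r = np.asarray(r, dtype=float)
        x = r / core_radius
        inside = x <= 1.0
        out = np.empty_like(x)
        jl_u = special.jv(self.l, self.u)
        kl_w = special.kv(self.l, self.w)
        out[inside] = special.jv(self.l, self.u * x[inside])
        # matched so R is continuous at r = a
        out[~inside] = jl_u / kl_w * special.kv(self.l, self.w * x[~inside])
        return out


def _dispersion(l: int, u: float, V: float) -> float:
    """Characteristic function whose roots are the guided LP_lm modes."""
    w = math.sqrt(max(V * V - u * u, 0.0))
    if w == 0.0:
        w = 1e-12
    return (
        u * special.jv(l + 1, u) * special.kv(l, w)
        - w * special.kv(l + 1, w) * special.jv(l, u)
    )


def solve_lp_modes(
    fiber: FiberSpec,
    wavelength: float | None = None,
    v_ceiling: float = DEFAULT_V_CEILING,
) -> list[LPMode]:
    """See :func:`_solve_lp_modes` — thin memoized wrapper."""
    lam = fiber.center_wavelength if wavelength is None else float(wavelength)
    return list(_solve_lp_modes(fiber, lam, v_ceiling))


@functools.lru_cache(maxsize=512)
def _solve_lp_modes(
    fiber: FiberSpec, wavelength: float, v_ceiling: float
) -> tuple[LPMode, ...]:
    """Solve the LP-mode dispersion relation of a step-index fiber.

    Returns every guided LP_lm mode (l >= 0; for l > 0 each solution stands
    for the degenerate cos/sin — here exp(±il·theta) — orientation pair).
    Roots of ``u·J_{l+1}(u)·K_l(w) = w·K_{l+1}(w)·J_l(u)`` with
    ``u² + w² = V²`` are bracketed on a fine grid and polished with Brent's
    method.

    Raises
    ------
    ValueError
        If V exceeds ``v_ceiling`` (scale the fiber down) or V is 0.
    """
    V = fiber.v_number(wavelength)
    if V <= 0:
        raise ValueError("degenerate fiber: V-number must be positive")
    if V > v_ceiling:
        raise ValueError(
            f"V = {V:.1f} exceeds the ceiling {v_ceiling}: ~{V*V/4:.0f} modes is "
            "beyond desk scale; use a scaled-down fiber (e.g. SCALED_FIBER) "
            "or raise v_ceiling explicitly"
        )
    k0 = 2.0 * math.pi / wavelength
    n1 = fiber.refractive_index_core
    n2 = fiber.n_clad

    modes: list[LPMode] = []
    l = 0
    while True:
        # scan for sign changes of the characteristic function on (0, V)
        us = np.linspace(1e-9, V - 1e-9, max(int(40 * V), 200))
        ws = np.sqrt(np.maximum(V * V - us * us, 1e-24))
        vals = us * special.jv(l + 1, us) * special.kv(l, ws) - ws * special.kv(
            l + 1, ws
        ) * special.jv(l, us)
        sign_change = vals[:-1] * vals[1:] < 0
        roots = [
            brentq(lambda u: _dispersion(l, u, V), us[i], us[i + 1])
            for i in np.nonzero(sign_change)[0]
        ]
        # discard spurious root at u ~ V (w -> 0, cutoff itself)
        roots = [u for u in roots if u < V - 1e-6]
        if not roots:
            if l == 0:
                # LP01 always exists; numerical grid should have found it
                break
            break
        for m, u in enumerate(sorted(roots), start=1):
            w = math.sqrt(V * V - u * u)
            b = 1.0 - (u / V) ** 2
            beta = k0 * math.sqrt(n2**2 + b * (n1**2 - n2**2))
            modes.append(LPMode(l=l, m=m, u=u, w=w, b=b, beta=beta))
        l += 1
    return tuple(modes)


@functools.lru_cache(maxsize=512)
def _mode_norms(fiber: FiberSpec, wavelength: float, v_ceiling: float) -> np.ndarray:
    """L2 norms of each guided mode profile over the transverse plane."""
    modes = _solve_lp_modes(fiber, wavelength, v_ceiling)
    r = np.linspace(0, 2.5 * fiber.core_radius, 600)
    norms = np.empty(len(modes))
    for i, mode in enumerate(modes):
        prof = mode.radial_profile(r, fiber.core_radius)
        # azimuthal integral of |exp(il theta)|^2 is 2*pi for every l
        norms[i] = math.sqrt(2.0 * math.pi * np.trapezoid(prof**2 * r, r))
    return norms


@functools.lru_cache(maxsize=64)
def _mode_profiles_fine(
    fiber: FiberSpec, wavelength: float, v_ceiling: float
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized radial profiles sampled on a fine grid, for interpolation."""
    modes = _solve_lp_modes(fiber, wavelength, v_ceiling)
    norms = _mode_norms(fiber, wavelength, v_ceiling)
    r_fine = np.linspace(0.0, 2.5 * fiber.core_radius, 1500)
    prof = np.empty((len(modes), r_fine.size))
    for i, mode in enumerate(modes):
        prof[i] = mode.radial_profile(r_fine, fiber.core_radius) / norms[i]
    return r_fine, prof


def azimuthal_mean_profile(
    image: np.ndarray, r_max: float | None = None, n_angles: int = 240
) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged radial intensity profile, subpixel-sampled.

    Samples the image on circles about its center with bilinear
    interpolation, so a cylindrically symmetric pattern yields a profile
    with near-zero azimuthal variance regardless of the pixel grid.
    """
    from scipy import ndimage

    img = np.asarray(image, dtype=float)
    n = img.shape[0]
    c = (n - 1) / 2.0
    if r_max is None:
        r_max = 0.48 * n
    angles = np.linspace(0, 2 * math.pi, n_angles, endpoint=False)
    radii = np.arange(0.0, r_max, 0.5)
    prof = np.empty(radii.size)
    for i, r in enumerate(radii):
        ys = c + r * np.sin(angles)
        xs = c + r * np.cos(angles)
        prof[i] = ndimage.map_coordinates(img, [ys, xs], order=1).mean()
    return radii, prof


def ring_radius_of(image: np.ndarray, core_radius_px: float | None = None) -> float:
    """Ring-radius descriptor rho: peak of the azimuthal-mean profile.

    For an on-axis source the profile peaks at the center (rho = 0); for
    off-axis sources the bright ring moves the peak outward. The descriptor
    saturates once the ring reaches the core edge.
    """
    img = np.asarray(image, dtype=float)
    if img.sum() <= 0:
        return 0.0
    from scipy import ndimage

    radii, prof = azimuthal_mean_profile(img, r_max=core_radius_px)
    smooth = ndimage.gaussian_filter1d(prof, 2.0)
    return float(radii[int(np.argmax(smooth))])


def azimuthal_symmetry_score(image: np.ndarray) -> float:
    """Cylindrical-symmetry score in (0, 1]; 1 = perfectly symmetric.

    Computed as 1/(1 + relvar) where relvar is the intensity-weighted mean
    over radii of the azimuthal variance/mean² of subpixel circle samples.
    """
    from scipy import ndimage

    img = np.asarray(image, dtype=float)
    n = img.shape[0]
    c = (n - 1) / 2.0
    angles = np.linspace(0, 2 * math.pi, 240, endpoint=False)
    radii = np.arange(1.0, 0.45 * n, 0.5)
    relvars = np.empty(radii.size)
    weights = np.empty(radii.size)
    for i, r in enumerate(radii):
        v = ndimage.map_coordinates(img, [c + r * np.sin(angles), c + r * np.cos(angles)], order=1)
        mu = v.mean()
        relvars[i] = v.var() / max(mu * mu, 1e-30)
        weights[i] = mu * r
    total = weights.sum()
    if total <= 0:
        return 1.0
    relvar = float((relvars * weights).sum() / total)
    return 1.0 / (1.0 + relvar)


def _facet_grid(fiber: FiberSpec, image_size: int, extent_factor: float = 2.4):
    """Physical (r, theta) coordinates of the proximal image pixels."""
    half = extent_factor * fiber.core_radius / 2.0
    coords = np.linspace(-half, half, image_size)
    x, y = np.meshgrid(coords, coords)
    return np.hypot(x, y), np.arctan2(y, x), x, y


def fingerprint_physical(
    fiber: FiberSpec,
    pos: SourcePosition,
    n_wavelengths: int = 11,
    seed: int = 0,
    image_size: int = 64,
    position_scale: float | None = None,
    phase_screen: np.ndarray | None = None,
    v_ceiling: float = DEFAULT_V_CEILING,
) -> FingerprintPattern:
    """Proximal-facet intensity fingerprint of a distal point source.

    The source at (d, azimuth) excites each guided mode in proportion to the
    mode amplitude at the source position; every mode propagates with its
    own phase over the fiber length, and intensities are averaged
    incoherently over ``n_wavelengths`` samples across the emission band.

    ``position_scale`` maps real-fiber µm to this (possibly scaled) fiber's
    µm; by default positions are scaled by core-radius ratio against the
    real 100 µm-core fiber. ``phase_screen`` (radians, broadcastable to the
    facet grid) models a thin scattering layer between source and facet.
    """
    if n_wavelengths < 1:
        raise ValueError("n_wavelengths must be >= 1")
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    scale = (
        position_scale
        if position_scale is not None
        else fiber.core_radius / REAL_FIBER.core_radius
    )
    d = pos.d * scale
    oof = pos.out_of_fov(fiber.core_radius / scale)

    r_grid, th_grid, x_grid, y_grid = _facet_grid(fiber, image_size)

    if d > FOV_CUTOFF * fiber.core_radius:
        # cladding decay leaves essentially nothing; return the flag
        img = np.zeros((image_size, image_size))
        return FingerprintPattern(image=img, ring_radius=0.0, out_of_fov=True, position=pos)

    intensity = np.zeros((image_size, image_size))
    for lam in fiber.wavelength_samples(n_wavelengths):
        modes = _solve_lp_modes(fiber, float(lam), v_ceiling)
        r_fine, prof_fine = _mode_profiles_fine(fiber, float(lam), v_ceiling)
        flat_r = r_grid.ravel()
        field = np.zeros((image_size, image_size), dtype=complex)
        length_um = fiber.length * 1000.0
        if phase_screen is None:
            # closed-form point coupling: c_{l,m} = R_{lm}(d) e^{-il phi0}
            for i, mode in enumerate(modes):
                prof_src = float(np.interp(d, r_fine, prof_fine[i]))
                prof_img = np.interp(flat_r, r_fine, prof_fine[i]).reshape(r_grid.shape)
                prop = np.exp(1j * (mode.beta * length_um % (2 * math.pi)))
                if mode.l == 0:
                    field += prof_src * prof_img * prop
                else:
                    ang = mode.l * (th_grid - pos.azimuth)
                    field += 2.0 * prof_src * prof_img * np.cos(ang) * prop
        else:
            # grid-based overlap coupling through the distal phase screen
            src_x = d * math.cos(pos.azimuth)
            src_y = d * math.sin(pos.azimuth)
            sigma = max(pos.diameter * scale / 2.355, fiber.core_radius / 40.0)
            src = np.exp(
                -(((x_grid - src_x) ** 2 + (y_grid - src_y) ** 2) / (2 * sigma**2))
            ).astype(complex)
            src *= np.exp(1j * np.broadcast_to(phase_screen, src.shape))
            dx = x_grid[0, 1] - x_grid[0, 0]
            for i, mode in enumerate(modes):
                prof_img = np.interp(flat_r, r_fine, prof_fine[i]).reshape(r_grid.shape)
                prop = np.exp(1j * (mode.beta * length_um % (2 * math.pi)))
                if mode.l == 0:
                    c = np.sum(prof_img * src) * dx * dx
                    field += c * prof_img * prop
                else:
                    for sgn in (1, -1):
                        psi = prof_img * np.exp(1j * sgn * mode.l * th_grid)
                        c = np.sum(np.conj(psi) * src) * dx * dx
                        field += c * psi * prop
        intensity += np.abs(field) ** 2
    intensity /= n_wavelengths
    core_px = image_size / 2.4  # facet extent is 2.4 core radii across
    return FingerprintPattern(
        image=intensity,
        ring_radius=ring_radius_of(intensity, core_radius_px=1.05 * core_px),
        out_of_fov=oof,
        position=pos,
    )


def fiber_geometry_summary(
    fiber: FiberSpec, power_at_distal: float, bead_diameter: float = 10.0
) -> dict:
    """Excitation-power arithmetic at the distal facet.

    Parameters are the total power emerging from the core (µW) and a bead
    diameter (µm); returns core area (mm²), excitation intensity (mW/mm²)
    and the power intercepted by one bead's cross-section (mW).
    """
    if power_at_distal < 0:
        raise ValueError("power must be nonnegative")
    if fiber.core_radius <= 0:
        raise ValueError("core radius must be positive")
    a_mm = fiber.core_radius * 1e-3
    core_area = math.pi * a_mm**2
    power_mw = power_at_distal * 1e-3
    intensity = power_mw / core_area
    bead_area = math.pi * (bead_diameter * 1e-3 / 2.0) ** 2
    return {
        "core_area_mm2": core_area,
        "intensity_mw_per_mm2": intensity,
        "power_per_bead_mw": intensity * bead_area,
    }
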