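"""Synthetic-data engine: phantoms, polychromatic projection, noise, view
sampling schemes, and fabrication of degraded prior images.

The generator emulates the physics that makes limited-data CT of bony anatomy
hard: a polychromatic X-ray source whose mean energy rises as it traverses
matter (beam hardening, producing cupping in homogeneous regions and dark
bands between dense structures), Poisson counting noise, and the four
acquisition scenarios — full sampling (SD), angular dose reduction (LD),
a contiguous limited span (LSA), and a random sparse subset of views (LNP).

Priors with controllable defects (half-size round-trip softening, blur, and
smooth "hallucination" bumps added or carved out) stand in for the output of
a learned artifact-correction model, including its failure modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import (
    Image2D,
    ProjectionGeometry,
    Sinogram,
    downsample_half,
    forward_project,
    upsample_bilinear,
)

__all__ = [
    "Spectrum",
    "Phantom",
    "SamplingScheme",
    "PriorSpec",
    "toy_spectrum",
    "make_phantom",
    "attenuation_image",
    "project_monochromatic",
    "project_polychromatic",
    "add_counting_noise",
    "subsample_projections",
    "fabricate_prior",
]

MATERIALS = ("air", "soft_tissue", "bone")


@dataclass
class Spectrum:
    """Energy-binned source weights plus per-material attenuation tables.

    ``material_atten[m][e]`` is the linear attenuation (mm⁻¹ at reference
    density) of material index ``m`` at energy bin ``e``.  Material indices
    follow :data:`MATERIALS` (0 air, 1 soft tissue, 2 bone).
    """

    energies_kev: np.ndarray
    weights: np.ndarray
    material_atten: np.ndarray  # (n_materials, n_energies)

    def __post_init__(self) -> None:
        self.energies_kev = np.asarray(self.energies_kev, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.material_atten = np.asarray(self.material_atten, dtype=np.float64)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("spectrum weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("spectrum weights must be nonnegative")
        if np.any(self.material_atten < 0):
            raise ValueError("attenuation coefficients must be nonnegative")
        if self.material_atten.shape[1] != self.energies_kev.size:
            raise ValueError("attenuation table width must match energy bins")

    @property
    def n_bins(self) -> int:
        return self.energies_kev.size


def toy_spectrum(n_bins: int = 4) -> Spectrum:
    """Bundled hand-set spectrum producing visible cupping and dark bands.

    Soft tissue is water-like; bone has a strong low-energy excess (its
    attenuation falls steeply with energy, the driver of hardening artifacts).
    Values are plausible mm⁻¹ magnitudes for the 30–80 keV range, not
    tabulated physics data.
    """
    energies = np.array([30.0, 45.0, 60.0, 80.0])
    weights = np.array([0.45, 0.25, 0.18, 0.12])
    atten = np.array(
        [
            [0.0, 0.0, 0.0, 0.0],  # air
            [0.048, 0.028, 0.021, 0.017],  # soft tissue (~water)
            [0.300, 0.115, 0.055, 0.032],  # bone
        ]
    )
    if n_bins == 1:
        # reference monochromatic bin at the mean energy
        e = np.array([np.sum(energies * weights)])
        a = np.array([[0.0], [np.sum(atten[1] * weights)], [np.sum(atten[2] * weights)]])
        return Spectrum(e, np.array([1.0]), a)
    if n_bins != 4:
        raise ValueError("bundled spectrum is available with 1 or 4 bins")
    return Spectrum(energies, weights, atten)


@dataclass
class Phantom:
    """Material label map plus relative density map on a square-pixel grid."""

    label_map: np.ndarray
    density_map: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=np.int64)
        self.density_map = np.asarray(self.density_map, dtype=np.float64)
        if self.label_map.shape != self.density_map.shape:
            raise ValueError("label and density maps must share a grid")
        if self.label_map.min() < 0 or self.label_map.max() >= len(MATERIALS):
            raise ValueError("labels must index the declared material set")
        if np.any(self.density_map < 0):
            raise ValueError("densities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape


def _grid(n: int, pixel_size: float):
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - c) * pixel_size, (c - yy) * pixel_size


def make_phantom(kind: str, n: int, pixel_size: float = 0.5, seed: int = 0) -> Phantom:
    """Deterministic test object on an ``n`` x ``n`` grid.

    ``disk``
        homogeneous soft-tissue disk (cupping test object).
    ``shell_skull``
        soft-tissue ellipse enclosed by a dense bone shell with seeded
        internal blobs — elicits dark bands between the shell crossings.
    ``blobs``
        a handful of random smooth soft-tissue blobs.
    """
    if n < 32:
        raise ValueError("phantom grid must be at least 32 pixels")
    rng = np.random.default_rng(seed)
    x, y = _grid(n, pixel_size)
    fov = n * pixel_size
    labels = np.zeros((n, n), dtype=np.int64)
    dens = np.zeros((n, n), dtype=np.float64)

    if kind == "disk":
        r = 0.35 * fov
        inside = x**2 + y**2 <= r**2
        labels[inside] = 1
        dens[inside] = 1.0
    elif kind == "shell_skull":
        a_out, b_out = 0.40 * fov, 0.32 * fov
        a_in, b_in = 0.345 * fov, 0.265 * fov
        outer = (x / a_out) ** 2 + (y / b_out) ** 2 <= 1.0
        inner = (x / a_in) ** 2 + (y / b_in) ** 2 <= 1.0
        labels[inner] = 1
        dens[inner] = 1.0
        shell = outer & ~inner
        labels[shell] = 2
        dens[shell] = 1.0
        for _ in range(4):  # internal soft-tissue blobs with density contrast
            bx = rng.uniform(-0.5, 0.5) * a_in
            by = rng.uniform(-0.5, 0.5) * b_in
            br = rng.uniform(0.04, 0.09) * fov
            amp = rng.uniform(0.1, 0.3) * rng.choice([-1.0, 1.0])
            blob = ((x - bx) ** 2 + (y - by) ** 2 <= br**2) & inner
            dens[blob] = np.clip(dens[blob] + amp, 0.2, None)
    elif kind == "blobs":
        for _ in range(6):
            bx = rng.uniform(-0.3, 0.3) * fov
            by = rng.uniform(-0.3, 0.3) * fov
            br = rng.uniform(0.05, 0.12) * fov
            blob = (x - bx) ** 2 + (y - by) ** 2 <= br**2
            labels[blob] = 1
            dens[blob] = np.maximum(dens[blob], rng.uniform(0.7, 1.2))
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return Phantom(labels, dens, pixel_size)


def attenuation_image(ph: Phantom, spec: Spectrum, energy_index: int) -> Image2D:
    """Linear-attenuation map (mm⁻¹) of the phantom at one energy bin."""
    if not 0 <= energy_index < spec.n_bins:
        raise ValueError("energy index out of range")
    mu = spec.material_atten[ph.label_map, energy_index] * ph.density_map
    return Image2D(mu, ph.pixel_size)


def project_monochromatic(
    ph: Phantom, geom: ProjectionGeometry, ref_energy_index: int, spec: Spectrum
) -> Sinogram:
    """Beam-hardening-free line integrals at a single reference energy."""
    return forward_project(attenuation_image(ph, spec, ref_energy_index), geom)


def project_polychromatic(
    ph: Phantom, geom: ProjectionGeometry, spec: Spectrum
) -> Sinogram:
    """Polychromatic log-transmission data: p = −ln Σ_E w(E) e^{−Σ_m μ_m(E) L_m}.

    Per-material path lengths ``L_m`` come from the same discrete projector as
    :func:`~picdl.geometry.forward_project`, so a one-bin spectrum reduces
    exactly to :func:`project_monochromatic`.
    """
    if spec.n_bins < 1:
        raise ValueError("spectrum needs at least one energy bin")
    # density-weighted path length per material
    paths = []
    for m in range(len(MATERIALS)):
        mask = (ph.label_map == m).astype(np.float64) * ph.density_map
        paths.append(forward_project(Image2D(mask, ph.pixel_size), geom).values)
    paths = np.stack(paths)  # (n_materials, n_angles, n_det)
    # transmission per energy bin
    exponent = np.einsum("me,mad->ead", spec.material_atten, paths)
    trans = np.einsum("e,ead->ad", spec.weights, np.exp(-exponent))
    return Sinogram(-np.log(trans), geom.angles.copy())


def add_counting_noise(sino: Sinogram, i0: float, seed: int = 0) -> Sinogram:
    """Poisson counting noise: counts ~ Poisson(i0·e^{−p}), p̂ = −ln(max(counts,1)/i0)."""
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(i0 * np.exp(-sino.values))
    p_hat = -np.log(np.maximum(counts, 1) / i0)
    return Sinogram(p_hat, sino.angles.copy())


@dataclass
class SamplingScheme:
    """One of the four acquisition scenarios applied to a full 360° sinogram.

    SD keeps everything; LD keeps every second view; LSA keeps a contiguous
    arc whose span is drawn uniformly from ``span_range`` (degrees) with a
    uniform start angle; LNP keeps a random subset of views whose size is
    drawn uniformly from ``count_range``.
    """

    kind: str
    span_range: tuple[float, float] = (90.0, 160.0)
    count_range: tuple[int, int] = (30, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("SD", "LD", "LSA", "LNP"):
            raise ValueError(f"unknown sampling scheme {self.kind!r}")
        if self.span_range[0] > self.span_range[1] or self.span_range[0] <= 0:
            raise ValueError("invalid span range")
        if self.count_range[0] > self.count_range[1] or self.count_range[0] < 1:
            raise ValueError("invalid count range")


def subsample_projections(sino: Sinogram, scheme: SamplingScheme) -> Sinogram:
    """Select views per the scheme; pure selection, retained rows bit-exact.

    The retained angle list travels with the returned sinogram; pair it with
    ``geom.with_angles(sub.angles)`` to get the matching restricted geometry.
    """
    n = sino.n_angles
    rng = np.random.default_rng(scheme.seed)
    if scheme.kind == "SD":
        idx = np.arange(n)
    elif scheme.kind == "LD":
        idx = np.arange(0, n, 2)
    elif scheme.kind == "LSA":
        span = rng.uniform(*scheme.span_range)
        start = rng.uniform(0.0, 360.0)
        rel = np.mod(sino.angles - start, 360.0)
        idx = np.nonzero(rel < span)[0]
        if idx.size < 2:
            raise ValueError("limited span retained fewer than 2 views")
    else:  # LNP
        count = int(rng.integers(scheme.count_range[0], scheme.count_range[1] + 1))
        if count > n:
            raise ValueError("requested more views than available")
        idx = np.sort(rng.choice(n, size=count, replace=False))
    return Sinogram(sino.values[idx].copy(), sino.angles[idx].copy())


@dataclass
class PriorSpec:
    """Degradation recipe for fabricating a prior image from a clean target.

    Emulates a learned prior: half-size round-trip softening (train-at-half-
    size protocol), Gaussian blur, and smooth radial "hallucination" bumps —
    additive for invented structures, subtractive for erased ones.
    """

    use_half_size_roundtrip: bool = True
    blur_sigma: float = 0.0
    hallucinations: list[tuple[tuple[int, int], float, float, str]] = field(
        default_factory=list
    )  # ((row, col), radius_px, amplitude_mm1, "add"|"remove")
    seed: int = 0

    def __post_init__(self) -> None:
        for (_, radius, amp, sign) in self.hallucinations:
            if radius <= 0:
                raise ValueError("hallucination radius must be positive")
            if not np.isfinite(amp):
                raise ValueError("hallucination amplitude must be finite")
            if sign not in ("add", "remove"):
                raise ValueError("hallucination sign must be 'add' or 'remove'")


def _radial_bump(shape: tuple[int, int], center: tuple[int, int], radius: float):
    """Compactly supported cosine-tapered bump, peak 1 at the centre pixel."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    bump = np.zeros(shape)
    inside = d < radius
    bump[inside] = 0.5 * (1.0 + np.cos(np.pi * d[inside] / radius))
    return bump


def fabricate_prior(target: Image2D, spec: PriorSpec) -> Image2D:
    """Degraded prior: half-size round-trip, blur, then hallucination bumps."""
    v = target.values.copy()
    if spec.use_half_size_roundtrip:
        if target.n_rows % 2 or target.n_cols % 2:
            raise ValueError("half-size round-trip requires even dimensions")
        half = downsample_half(Image2D(v, target.pixel_size))
        v = upsample_bilinear(half, target.n_rows, target.n_cols).values
    if spec.blur_sigma > 0:
        v = gaussian_filter(v, spec.blur_sigma, mode="nearest")
    for center, radius, amp, sign in spec.hallucinations:
        r, c = center
        if not (0 <= r < target.n_rows and 0 <= c < target.n_cols):
            raise ValueError("hallucination centre outside the image")
        if r - radius < 0 or r + radius >= target.n_rows or c - radius < 0 or c + radius >= target.n_cols:
            raise ValueError("hallucination blob extends outside the image")
        bump = _radial_bump(target.shape, center, radius) * amp
        v = v + bump if sign == "add" else v - bump
    return Image2D(v, target.pixel_size)
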