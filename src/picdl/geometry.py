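"""Projection geometry, matched forward/back projectors, FBP, and prior resampling.

The discrete forward operator ``F`` is a ray-driven Joseph projector (linear
interpolation between the two pixels adjacent to each ray/grid-line crossing,
weighted by the intersection length).  It is materialised once per geometry as
a sparse CSR matrix, so the backprojector is the *exact* matrix transpose and
the pair passes the adjoint dot-product test to rounding error by construction
— a requirement for the normal-operator ``FᵀF`` used inside the iterative
solver.

Conventions
-----------
* angles in degrees, counterclockwise, 0° along the +x axis;
* image indexed row-major, pixel centres, physical origin at the grid centre,
  +y pointing up (row 0 is the top of the image);
* lengths in mm, attenuation in mm⁻¹, line integrals dimensionless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from skimage.transform import resize as _sk_resize

__all__ = [
    "Image2D",
    "ProjectionGeometry",
    "Sinogram",
    "parallel_geometry",
    "fan_geometry",
    "argus_central_slice",
    "forward_project",
    "back_project",
    "fbp_reconstruct",
    "downsample_half",
    "upsample_bilinear",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Image2D:
    """A 2-D attenuation map (mm⁻¹) on a square-pixel grid.

    Parameters
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Attenuation coefficients; must be finite.
    pixel_size : float
        Physical pixel edge length in mm.
    """

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("Image2D requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Image2D values must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "Image2D":
        return Image2D(self.values.copy(), self.pixel_size)


@dataclass
class Sinogram:
    """Line-integral data: one row per view angle, one column per detector bin."""

    values: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("Sinogram requires a 2-D array (angles x bins)")
        if self.values.shape[0] != self.angles.shape[0]:
            raise ValueError("angle list length must match sinogram rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Sinogram values must be finite")

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]

    @property
    def n_det(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.angles.copy())


@dataclass
class ProjectionGeometry:
    """Acquisition description binding a detector to a reconstruction grid.

    ``beam_type`` is ``"parallel"`` or ``"fan"`` (flat equidistant detector,
    matching the central slice of a circular cone-beam flat-panel system).
    For fan beam, ``source_to_isocenter`` and ``source_to_detector`` are the
    mm distances from the focal spot to the rotation axis and to the detector.
    """

    beam_type: str
    angles: np.ndarray
    n_det: int
    det_spacing: float
    n_rows: int
    n_cols: int
    pixel_size: float
    source_to_isocenter: float | None = None
    source_to_detector: float | None = None
    _matrix: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.beam_type not in ("parallel", "fan"):
            raise ValueError(f"unknown beam_type {self.beam_type!r}")
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.angles.ndim != 1 or self.angles.size == 0:
            raise ValueError("angles must be a non-empty 1-D list")
        wrapped = np.mod(self.angles, 360.0)
        if np.any(np.diff(wrapped) <= 0) and np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing (modulo 360)")
        if self.n_det <= 0 or self.det_spacing <= 0 or self.pixel_size <= 0:
            raise ValueError("detector and pixel dimensions must be positive")
        if self.beam_type == "fan":
            if not self.source_to_isocenter or not self.source_to_detector:
                raise ValueError("fan beam requires source distances")
            if self.source_to_detector <= self.source_to_isocenter:
                raise ValueError("source_to_detector must exceed source_to_isocenter")

    @property
    def n_angles(self) -> int:
        return self.angles.size

    def image_matches(self, image: Image2D) -> bool:
        return (
            image.n_rows == self.n_rows
            and image.n_cols == self.n_cols
            and np.isclose(image.pixel_size, self.pixel_size)
        )

    def with_angles(self, angles: np.ndarray) -> "ProjectionGeometry":
        """Same scanner, different view set (system matrix cache dropped)."""
        return dataclasses.replace(self, angles=np.asarray(angles, float), _matrix=None)

    def system_matrix(self) -> sp.csr_matrix:
        """The discrete forward operator as a (n_angles*n_det, n_rows*n_cols) CSR."""
        if self._matrix is None:
            self._matrix = _joseph_matrix(self)
        return self._matrix


def parallel_geometry(
    n: int,
    pixel_size: float = 1.0,
    angles: np.ndarray | None = None,
    n_det: int | None = None,
    det_spacing: float | None = None,
) -> ProjectionGeometry:
    """Parallel-beam geometry around an ``n`` x ``n`` grid; detector covers the FOV diagonal."""
    if angles is None:
        angles = np.arange(0.0, 360.0, 1.0)
    if n_det is None:
        n_det = int(np.ceil(np.sqrt(2.0) * n)) + 2
    if det_spacing is None:
        det_spacing = pixel_size
    return ProjectionGeometry(
        "parallel", np.asarray(angles, float), n_det, det_spacing, n, n, pixel_size
    )


def fan_geometry(
    n: int,
    pixel_size: float = 1.0,
    angles: np.ndarray | None = None,
    source_to_isocenter: float | None = None,
    source_to_detector: float | None = None,
    n_det: int | None = None,
    det_spacing: float | None = None,
) -> ProjectionGeometry:
    """Flat-detector fan-beam geometry around an ``n`` x ``n`` grid."""
    if angles is None:
        angles = np.arange(0.0, 360.0, 1.0)
    fov = n * pixel_size
    if source_to_isocenter is None:
        source_to_isocenter = 2.0 * fov
    if source_to_detector is None:
        source_to_detector = 4.0 * fov
    mag = source_to_detector / source_to_isocenter
    if det_spacing is None:
        det_spacing = pixel_size * mag
    if n_det is None:
        n_det = int(np.ceil(np.sqrt(2.0) * n)) + 2
    return ProjectionGeometry(
        "fan",
        np.asarray(angles, float),
        n_det,
        det_spacing,
        n,
        n,
        pixel_size,
        source_to_isocenter=source_to_isocenter,
        source_to_detector=source_to_detector,
    )


def argus_central_slice(
    n: int = 128, pixel_size: float = 0.5, angles: np.ndarray | None = None
) -> ProjectionGeometry:
    """Fan-beam preset mirroring a small-animal flat-panel scanner central slice.

    Source-detector distance 370.95 mm, 0.2 mm detector pitch, 360 views/360°.
    """
    if angles is None:
        angles = np.arange(0.0, 360.0, 1.0)
    sdd = 370.95
    sid = sdd / 2.0
    n_det = max(int(np.ceil(np.sqrt(2.0) * n * pixel_size * (sdd / sid) / 0.2)) + 2, n)
    return ProjectionGeometry(
        "fan",
        np.asarray(angles, float),
        n_det,
        0.2,
        n,
        n,
        pixel_size,
        source_to_isocenter=sid,
        source_to_detector=sdd,
    )


# ---------------------------------------------------------------------------
# Joseph system matrix
# ---------------------------------------------------------------------------


def _ray_endpoints(geom: ProjectionGeometry, angle_deg: float):
    """Per-ray (origin point, unit direction) arrays, shape (n_det, 2) each."""
    th = np.deg2rad(angle_deg)
    t = (np.arange(geom.n_det) - (geom.n_det - 1) / 2.0) * geom.det_spacing
    e_t = np.array([-np.sin(th), np.cos(th)])  # detector axis
    d = np.array([np.cos(th), np.sin(th)])  # central ray direction
    if geom.beam_type == "parallel":
        p0 = t[:, None] * e_t[None, :]
        dirs = np.broadcast_to(d, (geom.n_det, 2)).copy()
    else:
        src = -geom.source_to_isocenter * d
        det_c = (geom.source_to_detector - geom.source_to_isocenter) * d
        pts = det_c[None, :] + t[:, None] * e_t[None, :]
        dirs = pts - src[None, :]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        p0 = np.broadcast_to(src, (geom.n_det, 2)).copy()
    return p0, dirs


def _joseph_entries_x_major(p0, dirs, rays, geom, angle_index):
    """COO triplets for rays stepping through image columns (|dx| >= |dy|)."""
    nr, nc, ps = geom.n_rows, geom.n_cols, geom.pixel_size
    xs = (np.arange(nc) - (nc - 1) / 2.0) * ps  # column centres
    slope = dirs[rays, 1] / dirs[rays, 0]
    # ray y at each column centre
    y = p0[rays, 1][:, None] + (xs[None, :] - p0[rays, 0][:, None]) * slope[:, None]
    rr = (nr - 1) / 2.0 - y / ps  # continuous row coordinate
    w = ps / np.abs(dirs[rays, 0])  # path length per column crossing
    r0 = np.floor(rr).astype(np.int64)
    frac = rr - r0
    ray_idx = (angle_index * geom.n_det + rays)[:, None]
    cols_idx = np.broadcast_to(np.arange(nc)[None, :], rr.shape)
    out_r, out_c, out_v = [], [], []
    for rr_i, coef in ((r0, 1.0 - frac), (r0 + 1, frac)):
        ok = (rr_i >= 0) & (rr_i < nr) & (coef > 0)
        out_r.append(np.broadcast_to(ray_idx, rr.shape)[ok])
        out_c.append((rr_i * nc + cols_idx)[ok])
        out_v.append((coef * w[:, None])[ok])
    return out_r, out_c, out_v


def _joseph_entries_y_major(p0, dirs, rays, geom, angle_index):
    """COO triplets for rays stepping through image rows (|dy| > |dx|)."""
    nr, nc, ps = geom.n_rows, geom.n_cols, geom.pixel_size
    ys = ((nr - 1) / 2.0 - np.arange(nr)) * ps  # row centres
    slope = dirs[rays, 0] / dirs[rays, 1]
    x = p0[rays, 0][:, None] + (ys[None, :] - p0[rays, 1][:, None]) * slope[:, None]
    cc = x / ps + (nc - 1) / 2.0  # continuous column coordinate
    w = ps / np.abs(dirs[rays, 1])
    c0 = np.floor(cc).astype(np.int64)
    frac = cc - c0
    ray_idx = (angle_index * geom.n_det + rays)[:, None]
    rows_idx = np.broadcast_to(np.arange(nr)[None, :], cc.shape)
    out_r, out_c, out_v = [], [], []
    for cc_i, coef in ((c0, 1.0 - frac), (c0 + 1, frac)):
        ok = (cc_i >= 0) & (cc_i < nc) & (coef > 0)
        out_r.append(np.broadcast_to(ray_idx, cc.shape)[ok])
        out_c.append((rows_idx * nc + cc_i)[ok])
        out_v.append((coef * w[:, None])[ok])
    return out_r, out_c, out_v


def _joseph_matrix(geom: ProjectionGeometry) -> sp.csr_matrix:
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    all_rays = np.arange(geom.n_det)
    for a, ang in enumerate(geom.angles):
        p0, dirs = _ray_endpoints(geom, ang)
        xm = np.abs(dirs[:, 0]) >= np.abs(dirs[:, 1])
        for mask, fn in ((xm, _joseph_entries_x_major), (~xm, _joseph_entries_y_major)):
            if not np.any(mask):
                continue
            r, c, v = fn(p0, dirs, all_rays[mask], geom, a)
            rows.extend(r)
            cols.extend(c)
            vals.extend(v)
    shape = (geom.n_angles * geom.n_det, geom.n_rows * geom.n_cols)
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=shape,
    )
    return mat.tocsr()


# ---------------------------------------------------------------------------
# projection operators
# ---------------------------------------------------------------------------


def forward_project(image: Image2D, geom: ProjectionGeometry) -> Sinogram:
    """Line integrals of ``image`` along every (angle, detector-bin) ray."""
    if not geom.image_matches(image):
        raise ValueError(
            f"image grid {image.shape}@{image.pixel_size} does not match geometry "
            f"binding ({geom.n_rows},{geom.n_cols})@{geom.pixel_size}"
        )
    p = geom.system_matrix() @ image.values.ravel()
    return Sinogram(p.reshape(geom.n_angles, geom.n_det), geom.angles.copy())


def back_project(sino: Sinogram, geom: ProjectionGeometry) -> Image2D:
    """Exact transpose of :func:`forward_project` (matched adjoint)."""
    if sino.values.shape != (geom.n_angles, geom.n_det):
        raise ValueError(
            f"sinogram shape {sino.values.shape} does not match geometry "
            f"({geom.n_angles},{geom.n_det})"
        )
    u = geom.system_matrix().T @ sino.values.ravel()
    return Image2D(u.reshape(geom.n_rows, geom.n_cols), geom.pixel_size)


# ---------------------------------------------------------------------------
# filtered backprojection
# ---------------------------------------------------------------------------


def _ramp_filter(n_det: int, det_spacing: float, filter_name: str) -> np.ndarray:
    # Discretised Ram-Lak: FFT of the band-limited spatial kernel
    # h[0] = 1/(4 dt^2), h[n] = -1/(pi n dt)^2 for odd n, 0 for even n.
    # Unlike sampling |nu| directly, this keeps the DC response consistent
    # with the finite detector sampling (no background bias).
    n_pad = 1 << int(np.ceil(np.log2(max(2 * n_det, 2))))
    k = np.concatenate([np.arange(n_pad // 2 + 1), np.arange(n_pad // 2 - 1, 0, -1)])
    h = np.zeros(n_pad)
    h[0] = 1.0 / (4.0 * det_spacing**2)
    odd = k % 2 == 1
    h[odd] = -1.0 / (np.pi * k[odd] * det_spacing) ** 2
    ramp = np.real(np.fft.rfft(h)) * det_spacing  # units 1/mm
    if filter_name == "hann":
        freqs = np.fft.rfftfreq(n_pad, d=det_spacing)
        f_max = 0.5 / det_spacing
        ramp *= 0.5 * (1.0 + np.cos(np.pi * freqs / f_max))
    elif filter_name != "ramlak":
        raise ValueError(f"unknown filter {filter_name!r}")
    return ramp


def _view_weights_deg(angles: np.ndarray) -> np.ndarray:
    """Per-view angular weights: mean of adjacent gaps, end gaps replicated."""
    if angles.size == 1:
        return np.array([1.0])
    gaps = np.diff(np.sort(angles))
    padded = np.concatenate([[gaps[0]], gaps, [gaps[-1]]])
    return 0.5 * (padded[:-1] + padded[1:])


def fbp_reconstruct(
    sino: Sinogram, geom: ProjectionGeometry, filter_name: str = "ramlak"
) -> Image2D:
    """Ramp-filtered backprojection (2-D stand-in for the central slice of FDK).

    Views are weighted by their actual angular spacing, so non-uniform view
    sets (random subsets, contiguous arcs) are handled without any gap
    compensation; a missing arc simply contributes nothing.  The global scale
    assumes the doubly-covered 360° parallel case (each line measured twice),
    which is the acquisition this toolkit simulates.  For fan beam, the
    projections are cosine-weighted and frequencies are taken at the
    isocenter-referred detector pitch; backprojection through the matched
    adjoint omits the exact fan distance weighting, which is adequate for the
    small fan angles of the bundled presets.
    """
    if sino.values.shape != (geom.n_angles, geom.n_det):
        raise ValueError("sinogram shape does not match geometry")
    if geom.n_angles < 2:
        raise ValueError("FBP requires at least 2 view angles")

    values = sino.values
    dt = geom.det_spacing
    if geom.beam_type == "fan":
        mag = geom.source_to_detector / geom.source_to_isocenter
        t = (np.arange(geom.n_det) - (geom.n_det - 1) / 2.0) * dt
        cosw = geom.source_to_detector / np.sqrt(geom.source_to_detector**2 + t**2)
        values = values * cosw[None, :]
        dt = dt / mag  # isocenter-referred pitch

    ramp = _ramp_filter(geom.n_det, dt, filter_name)
    n_pad = 2 * (ramp.size - 1)
    spec = np.fft.rfft(values, n=n_pad, axis=1)
    filtered = np.fft.irfft(spec * ramp[None, :], n=n_pad, axis=1)[:, : geom.n_det]

    w_rad = np.deg2rad(_view_weights_deg(geom.angles))
    weighted = Sinogram(filtered * w_rad[:, None], geom.angles.copy())
    bp = back_project(weighted, geom)
    # Joseph-adjoint backprojection of an interpolated profile carries a
    # ps^2/dt footprint mass; 1/2 accounts for the doubly covered full circle.
    scale = 0.5 * dt / geom.pixel_size**2
    return Image2D(bp.values * scale, geom.pixel_size)


# ---------------------------------------------------------------------------
# prior-protocol resampling
# ---------------------------------------------------------------------------


def downsample_half(image: Image2D) -> Image2D:
    """Half-size image by averaging each 2x2 pixel neighbourhood."""
    nr, nc = image.shape
    if nr % 2 or nc % 2:
        raise ValueError("downsample_half requires even dimensions; pad or crop first")
    v = image.values.reshape(nr // 2, 2, nc // 2, 2).mean(axis=(1, 3))
    return Image2D(v, image.pixel_size * 2.0)


def upsample_bilinear(image: Image2D, target_rows: int, target_cols: int) -> Image2D:
    """Bilinear upsampling to (target_rows, target_cols); constants preserved."""
    nr, nc = image.shape
    if target_rows < nr or target_cols < nc:
        raise ValueError("target size must be at least the source size")
    v = _sk_resize(
        image.values,
        (target_rows, target_cols),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    new_ps = image.pixel_size * nr / target_rows
    return Image2D(np.asarray(v, dtype=np.float64), new_ps)
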