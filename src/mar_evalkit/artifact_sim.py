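"""Fan-beam artifact simulation: forward projection, physics-motivated
sinogram corruption, and filtered back projection.

The *Artifacts* volumes are manufactured slice-wise: each axial slice of the
Reference volume is forward projected with an equiangular fan-beam geometry
(984 views over 360 degrees, 920 detector bins, source-to-center distance
59.5 cm in the clinical profile), the line integrals along rays crossing
metal are corrupted with a two-bin polychromatic transmission model plus
Poisson photon noise (beam hardening + photon starvation), and the corrupted
sinogram is reconstructed with filtered back projection (rebinning to
parallel geometry, Hann-apodized ramp filter).

HU <-> attenuation conversion uses the standard CT definition
``mu = mu_water * (1 + HU/1000)`` floored at zero, with
``mu_water = 0.0193 / mm`` by default (~70 keV effective energy).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .errors import GeometryError, ValidationError
from .volume_io import CTVolume, VoxelMask, clamp_hu

MU_WATER_PER_MM = 0.0193

# fan coverage target: 920 bins cover a 400 mm FOV with a 10% margin at
# isocenter, i.e. a coverage radius of 220 mm
COVERAGE_RADIUS_MM = 220.0


@dataclasses.dataclass(frozen=True)
class FanBeamGeometry:
    """Equiangular fan-beam projection geometry.

    n_views: projection views over a full rotation.
    n_bins: detector bins per view.
    source_center_cm: distance from the X-ray source to the rotation center.
    coverage_radius_mm: object radius the fan must cover (fan angle is
        derived from it; defaults to 220 mm = half of a 400 mm FOV + 10%).
    """

    n_views: int = 984
    n_bins: int = 920
    source_center_cm: float = 59.5
    coverage_radius_mm: float = COVERAGE_RADIUS_MM

    def __post_init__(self):
        if self.n_views <= 0 or self.n_bins <= 0:
            raise ValidationError("n_views and n_bins must be positive")
        if self.source_center_mm <= self.coverage_radius_mm:
            raise GeometryError(
                f"source-to-center distance {self.source_center_mm} mm must exceed "
                f"the coverage radius {self.coverage_radius_mm} mm"
            )

    @property
    def source_center_mm(self) -> float:
        return self.source_center_cm * 10.0

    @property
    def source_detector_mm(self) -> float:
        # detector on the far side of the rotation center, symmetric geometry
        return 2.0 * self.source_center_mm

    @property
    def gamma_max(self) -> float:
        """Half fan angle (rad) covering ``coverage_radius_mm`` at isocenter."""
        return math.asin(self.coverage_radius_mm / self.source_center_mm)

    @property
    def detector_span_deg(self) -> float:
        return math.degrees(2.0 * self.gamma_max)

    @property
    def bin_spacing_rad(self) -> float:
        return 2.0 * self.gamma_max / self.n_bins

    @property
    def view_angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_views) / self.n_views

    @property
    def bin_angles(self) -> np.ndarray:
        """Fan angles of bin centers, symmetric about the central ray."""
        return (-self.gamma_max + (np.arange(self.n_bins) + 0.5) * self.bin_spacing_rad)

    def half_profile(self) -> "FanBeamGeometry":
        """The desk-scale profile: half the views and bins, same fan."""
        return dataclasses.replace(self, n_views=self.n_views // 2, n_bins=self.n_bins // 2)


@dataclasses.dataclass
class Sinogram:
    """Line integrals of linear attenuation (unitless) for one slice."""

    data: np.ndarray  # (n_views, n_bins)
    geometry: FanBeamGeometry
    slice_index: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (self.geometry.n_views, self.geometry.n_bins)
        if self.data.shape != expected:
            raise ValidationError(f"sinogram shape {self.data.shape} != geometry {expected}")
        if not np.isfinite(self.data).all():
            raise ValidationError("sinogram contains non-finite values")


@dataclasses.dataclass
class CorruptionModel:
    """Polychromatic transmission + Poisson noise applied along metal traces.

    i0: incident photon count per ray.
    spectrum: (energy keV, weight) pairs, weights summing to 1; the lowest
        energy bin is the one whose metal attenuation is scaled.  The
        default weights are low-energy-dominant, as for a 120 kVp beam.
    metal_mu_scale: extra multiplier on the metal line integral in the
        low-energy bin (beam hardening surrogate).
    metal_density_scale: multiplier on the metal line integral in every
        bin — the stored metal HU is clipped by the 12-bit CT range, so the
        physical attenuation of a filling is several times what its stored
        value implies.  This term drives photon starvation.
    seed: seeds the Poisson noise.
    poisson_noise: disable to evaluate the noiseless closed form.
    """

    i0: float = 2.0e5
    spectrum: Tuple[Tuple[float, float], ...] = ((50.0, 0.7), (80.0, 0.3))
    metal_mu_scale: float = 2.5
    metal_density_scale: float = 8.0
    seed: int = 0
    poisson_noise: bool = True

    def __post_init__(self):
        self.spectrum = tuple((float(e), float(w)) for e, w in self.spectrum)
        if self.i0 <= 0:
            raise ValidationError("i0 must be positive")
        total = sum(w for _, w in self.spectrum)
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValidationError(f"spectrum weights must sum to 1, got {total}")


def hu_to_mu(hu, mu_water: float = MU_WATER_PER_MM):
    """Linear attenuation per mm from HU: ``mu_water * (1 + HU/1000)``, floored at 0."""
    if mu_water <= 0:
        raise ValidationError("mu_water must be positive")
    return np.maximum(mu_water * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0), 0.0)


def mu_to_hu(mu, mu_water: float = MU_WATER_PER_MM):
    """Inverse of :func:`hu_to_mu` (without the floor)."""
    return 1000.0 * (np.asarray(mu, dtype=np.float64) / mu_water - 1.0)


@njit(cache=True)
def _fp_kernel(mu, dx, dy, dsrc, betas, gammas, r_int, step):  # pragma: no cover - jitted
    nv = betas.size
    nb = gammas.size
    ny, nx = mu.shape
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    out = np.zeros((nv, nb))
    for i in range(nv):
        b = betas[i]
        sx = dsrc * math.cos(b)
        sy = dsrc * math.sin(b)
        for j in range(nb):
            g = gammas[j]
            ux = -math.cos(b + g)
            uy = -math.sin(b + g)
            s_perp = dsrc * math.sin(g)
            h2 = r_int * r_int - s_perp * s_perp
            if h2 <= 0.0:
                continue
            h = math.sqrt(h2)
            tc = dsrc * math.cos(g)
            t0 = tc - h
            nsteps = int(2.0 * h / step) + 1
            dt = 2.0 * h / nsteps
            acc = 0.0
            for k in range(nsteps):
                t = t0 + (k + 0.5) * dt
                px = sx + t * ux
                py = sy + t * uy
                fx = px / dx + cx
                fy = py / dy + cy
                ix = int(math.floor(fx))
                iy = int(math.floor(fy))
                if ix < -1 or ix > nx - 1 or iy < -1 or iy > ny - 1:
                    continue
                wx = fx - ix
                wy = fy - iy
                v00 = mu[iy, ix] if (0 <= ix < nx and 0 <= iy < ny) else 0.0
                v01 = mu[iy, ix + 1] if (0 <= ix + 1 < nx and 0 <= iy < ny) else 0.0
                v10 = mu[iy + 1, ix] if (0 <= ix < nx and 0 <= iy + 1 < ny) else 0.0
                v11 = mu[iy + 1, ix + 1] if (0 <= ix + 1 < nx and 0 <= iy + 1 < ny) else 0.0
                acc += (
                    v00 * (1 - wx) * (1 - wy)
                    + v01 * wx * (1 - wy)
                    + v10 * (1 - wx) * wy
                    + v11 * wx * wy
                )
            out[i, j] = acc * dt
    return out


@njit(cache=True)
def _bp_kernel(q, thetas, s0, ds, xs, ys):  # pragma: no cover - jitted
    ntheta, ns = q.shape
    ny = ys.size
    nx = xs.size
    out = np.zeros((ny, nx))
    for k in range(ntheta):
        c = math.cos(thetas[k])
        s = math.sin(thetas[k])
        for iy in range(ny):
            yc = ys[iy] * s
            for ix in range(nx):
                t = (xs[ix] * c + yc - s0) / ds
                it = int(math.floor(t))
                if it < 0 or it >= ns - 1:
                    continue
                w = t - it
                out[iy, ix] += q[k, it] * (1 - w) + q[k, it + 1] * w
    return out


def forward_project(
    slice_hu: np.ndarray,
    spacing: Tuple[float, float],
    geom: FanBeamGeometry,
    mu_water: float = MU_WATER_PER_MM,
    slice_index: int = 0,
) -> Sinogram:
    """Fan-beam forward projection of one axial slice.

    Each sinogram element is the line integral of ``hu_to_mu(slice)`` along
    the source-to-bin ray, computed by interpolated ray marching with a step
    of half the pixel pitch.  Raises :class:`GeometryError` if attenuating
    material lies outside the fan coverage (truncation).
    """
    slice_hu = np.asarray(slice_hu, dtype=np.float64)
    if slice_hu.ndim != 2:
        raise ValidationError(f"expected a 2D slice, got shape {slice_hu.shape}")
    if not np.isfinite(slice_hu).all():
        raise ValidationError("slice contains non-finite values")
    dy, dx = (float(s) for s in spacing)
    mu = hu_to_mu(slice_hu, mu_water)
    ny, nx = mu.shape
    iy, ix = np.nonzero(mu > 1e-12)
    if iy.size:
        px = (ix - (nx - 1) / 2.0) * dx
        py = (iy - (ny - 1) / 2.0) * dy
        rmax = float(np.sqrt(px**2 + py**2).max())
        if rmax > geom.coverage_radius_mm:
            raise GeometryError(
                f"object radius {rmax:.1f} mm exceeds fan coverage "
                f"{geom.coverage_radius_mm:.1f} mm (truncated fan)"
            )
    step = 0.5 * min(dx, dy)
    data = _fp_kernel(
        np.ascontiguousarray(mu),
        dx,
        dy,
        geom.source_center_mm,
        geom.view_angles,
        geom.bin_angles,
        geom.coverage_radius_mm,
        step,
    )
    return Sinogram(data=data, geometry=geom, slice_index=slice_index)


def corrupt_sinogram(
    sino: Sinogram,
    metal_trace: np.ndarray,
    model: CorruptionModel,
    metal_path: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> Sinogram:
    """Apply the polychromatic + Poisson corruption model along metal traces.

    Per ray the detected intensity is ``I = i0 * sum_k w_k * exp(-p_k)``
    with per-energy-bin path ``p_k``; in the lowest-energy bin the metal
    line integral is scaled by ``metal_mu_scale``.  ``metal_path`` carries
    the metal-only line integrals (same shape as the sinogram); if omitted,
    the entire path of trace rays is treated as metal.  Poisson noise is
    applied with the model seed; intensities below one photon are clamped
    (photon starvation).  With no metal and ``i0 -> inf`` the corruption is
    the identity.
    """
    trace = np.asarray(metal_trace, dtype=bool)
    if trace.shape != sino.data.shape:
        raise ValidationError(f"trace shape {trace.shape} != sinogram shape {sino.data.shape}")
    p = sino.data
    if metal_path is None:
        p_metal = np.where(trace, p, 0.0)
    else:
        p_metal = np.asarray(metal_path, dtype=np.float64)
        if p_metal.shape != p.shape:
            raise ValidationError("metal_path shape mismatch")
    energies = [e for e, _ in model.spectrum]
    low = int(np.argmin(energies))
    intensity = np.zeros_like(p)
    for k, (_, w) in enumerate(model.spectrum):
        scale = model.metal_density_scale * (model.metal_mu_scale if k == low else 1.0)
        pk = p + (scale - 1.0) * p_metal
        intensity += w * np.exp(-np.clip(pk, 0.0, 700.0))
    intensity *= model.i0
    if model.poisson_noise:
        if rng is None:
            rng = np.random.default_rng(model.seed)
        intensity = rng.poisson(intensity).astype(np.float64)
    corrupted = -np.log(np.maximum(intensity, 1.0) / model.i0)
    corrupted = np.maximum(corrupted, 0.0)
    return Sinogram(data=corrupted, geometry=sino.geometry, slice_index=sino.slice_index)


def _ramp_kernel(ns: int, ds: float) -> np.ndarray:
    """Band-limited spatial ramp filter kernel (length 2*ns-1)."""
    n = np.arange(-(ns - 1), ns)
    h = np.zeros(n.size)
    h[n == 0] = 1.0 / (4.0 * ds * ds)
    odd = n % 2 != 0
    h[odd] = -1.0 / (np.pi * n[odd] * ds) ** 2
    return h


def _filter_projections(p: np.ndarray, ds: float, apodization: str = "hann") -> np.ndarray:
    """Ramp-filter each row of ``p`` (parallel projections over s)."""
    ntheta, ns = p.shape
    from scipy.fft import next_fast_len

    h = _ramp_kernel(ns, ds)
    nfft = next_fast_len(ns + h.size - 1)
    H = np.fft.rfft(h, nfft)
    if apodization == "hann":
        freq = np.arange(H.size) / nfft  # cycles per sample, up to 0.5
        window = 0.5 * (1.0 + np.cos(2.0 * np.pi * freq))  # 1 at DC, 0 at Nyquist
        H = H * window
    elif apodization != "ramp":
        raise ValidationError(f"unknown apodization {apodization!r}")
    P = np.fft.rfft(p, nfft, axis=1)
    q = np.fft.irfft(P * H[None, :], nfft, axis=1)
    return q[:, ns - 1 : 2 * ns - 1] * ds


def _rebin_to_parallel(sino: Sinogram) -> Tuple[np.ndarray, np.ndarray, float, float]:
    """Rebin equiangular fan data to a parallel (theta, s) grid.

    Returns (parallel sinogram, theta array, s0, ds).  A fan ray at source
    angle beta and fan angle gamma is the parallel ray with
    ``theta = beta + gamma - pi/2`` and ``s = d * sin(gamma)``.
    """
    geom = sino.geometry
    d = geom.source_center_mm
    smax = geom.coverage_radius_mm
    ns = geom.n_bins
    ntheta = geom.n_views
    ds = 2.0 * smax / ns
    s = -smax + (np.arange(ns) + 0.5) * ds
    thetas = 2.0 * np.pi * np.arange(ntheta) / ntheta
    gamma = np.arcsin(np.clip(s / d, -1.0, 1.0))  # (ns,)
    beta = thetas[:, None] - gamma[None, :] + np.pi / 2.0  # (ntheta, ns)
    # fractional indices on the fan grid
    dbeta = 2.0 * np.pi / geom.n_views
    fb = np.mod(beta, 2.0 * np.pi) / dbeta
    fg = (gamma + geom.gamma_max) / geom.bin_spacing_rad - 0.5
    ib = np.floor(fb).astype(np.int64)
    wb = fb - ib
    ib0 = np.mod(ib, geom.n_views)
    ib1 = np.mod(ib + 1, geom.n_views)
    fg = np.clip(fg, 0.0, geom.n_bins - 1.0)
    ig = np.clip(np.floor(fg).astype(np.int64), 0, geom.n_bins - 2)
    wg = fg - ig
    ig_b = np.broadcast_to(ig[None, :], fb.shape)
    wg_b = np.broadcast_to(wg[None, :], fb.shape)
    data = sino.data
    par = (
        data[ib0, ig_b] * (1 - wb) * (1 - wg_b)
        + data[ib0, ig_b + 1] * (1 - wb) * wg_b
        + data[ib1, ig_b] * wb * (1 - wg_b)
        + data[ib1, ig_b + 1] * wb * wg_b
    )
    return par, thetas, float(s[0]), ds


def fbp_reconstruct(
    sino: Sinogram,
    out_shape: Tuple[int, int],
    spacing: Tuple[float, float],
    mu_water: float = MU_WATER_PER_MM,
    apodization: str = "hann",
) -> np.ndarray:
    """Filtered back projection of one fan-beam sinogram, returned in HU.

    Fan data are rebinned to parallel geometry, ramp filtered (Hann
    apodized by default) and backprojected; the reconstructed attenuation is
    converted back to HU with the inverse of :func:`hu_to_mu`.
    """
    par, thetas, s0, ds = _rebin_to_parallel(sino)
    q = _filter_projections(par, ds, apodization)
    ny, nx = out_shape
    dy, dx = (float(v) for v in spacing)
    xs = (np.arange(nx) - (nx - 1) / 2.0) * dx
    ys = (np.arange(ny) - (ny - 1) / 2.0) * dy
    dtheta = 2.0 * np.pi / thetas.size
    # the 360-degree parallel set covers each line twice -> weight 1/2
    mu = _bp_kernel(np.ascontiguousarray(q), thetas, s0, ds, xs, ys) * (dtheta / 2.0)
    # pixels outside the fan coverage circle are not measured: report air
    rr = ys[:, None] ** 2 + xs[None, :] ** 2
    mu[rr > sino.geometry.coverage_radius_mm**2] = 0.0
    return mu_to_hu(mu, mu_water)


def metal_trace_threshold() -> float:
    """Threshold on metal-only line integrals defining the metal trace."""
    return 1e-9


def simulate_artifact_volume(
    ref: CTVolume,
    metal_mask: VoxelMask,
    geom: FanBeamGeometry,
    model: CorruptionModel,
    mu_water: float = MU_WATER_PER_MM,
) -> CTVolume:
    """Manufacture the *Artifacts* volume from a Reference volume.

    Slices intersecting the metal mask are forward projected, corrupted
    along the metal trace and reconstructed; metal-free slices pass through
    unchanged.  Deterministic given the inputs and ``model.seed``.
    """
    ref.require_aligned(metal_mask, "metal mask")
    dz, dy, dx = ref.spacing
    out = ref.data.astype(np.float64).copy()
    seed_seq = np.random.SeedSequence([int(model.seed) % (2**31), 0x5A17])
    child_seeds = seed_seq.spawn(ref.shape[0])
    for z in range(ref.shape[0]):
        mslice = metal_mask.data[z]
        if not mslice.any():
            continue
        sino = forward_project(ref.data[z], (dy, dx), geom, mu_water, slice_index=z)
        mu_metal = np.where(mslice, hu_to_mu(ref.data[z], mu_water), 0.0)
        p_metal = _fp_kernel(
            np.ascontiguousarray(mu_metal),
            dx,
            dy,
            geom.source_center_mm,
            geom.view_angles,
            geom.bin_angles,
            geom.coverage_radius_mm,
            0.5 * min(dx, dy),
        )
        trace = p_metal > metal_trace_threshold()
        rng = np.random.default_rng(child_seeds[z])
        corrupted = corrupt_sinogram(sino, trace, model, metal_path=p_metal, rng=rng)
        out[z] = fbp_reconstruct(corrupted, ref.shape[1:], (dy, dx), mu_water)
    out = clamp_hu(out)
    return ref.copy(data=out)
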