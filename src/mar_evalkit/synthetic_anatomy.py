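"""Synthetic head-and-neck CT phantoms with addressable teeth.

Generates artifact-free volumes that stand in for clinical head CT: an
elliptical soft-tissue body in air, an oral air cavity, mandible/maxilla
bone arcs, sixteen teeth on an elliptical dental arch, a pseudo clinical
target volume (CTV) at the tongue base posterior to the arch, and
placeholder spinal-cord / parotid masks.  Pseudo-dental fillings are
inserted by uniformly assigning a metal HU value (default 4000 HU) to a
selected subset of teeth — four in the ``m4`` scheme, eight in ``m8``,
with the m4 selection always nested inside the m8 selection of the same
seed so the two schemes form a paired design per case.

All geometry is drawn deterministically from the config seed; the same
config yields voxel-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, ValidationError
from .volume_io import CTVolume, VoxelMask

DEFAULT_TISSUE_HU: Dict[str, float] = {"air": -1000.0, "soft": 40.0, "bone": 700.0, "tooth": 1200.0}

N_TEETH = 16


@dataclasses.dataclass
class PhantomConfig:
    """Acquisition envelope and tissue model for one synthetic case.

    matrix: in-plane size in voxels (512 clinical; small values for tests).
    fov_mm: field of view, must lie in [350, 400] mm.
    slice_thickness_mm: in [1, 3] mm.
    n_slices: number of axial slices.
    tissue_hu: HU per tissue class (air/soft/bone/tooth).
    noise_sd_hu: additive Gaussian HU noise inside non-air tissue (0 in air).
    psf_sigma_px: in-plane Gaussian point-spread (pixels) applied to the
        anatomy before noise — clinical CT is bandlimited by the scanner
        reconstruction kernel and contains no super-Nyquist edges.
    seed: fully determines the generated volume and masks.
    """

    matrix: int = 512
    fov_mm: float = 370.0
    slice_thickness_mm: float = 2.0
    n_slices: int = 24
    tissue_hu: Dict[str, float] = dataclasses.field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    noise_sd_hu: float = 10.0
    psf_sigma_px: float = 0.7
    seed: int = 0
    # base anatomy (mm); jittered per seed
    body_halfaxes_mm: Tuple[float, float] = (95.0, 80.0)  # (y anterior-posterior, x lateral)
    arch_halfaxes_mm: Tuple[float, float] = (40.0, 52.0)  # (y, x)
    arch_center_y_mm: float = 38.0
    tooth_radius_mm: float = 4.0

    def __post_init__(self):
        if not (350.0 <= self.fov_mm <= 400.0):
            raise ConfigurationError(f"fov_mm must be in [350, 400], got {self.fov_mm}")
        if not (1.0 <= self.slice_thickness_mm <= 3.0):
            raise ConfigurationError(f"slice_thickness_mm must be in [1, 3], got {self.slice_thickness_mm}")
        if self.matrix < 32:
            raise ConfigurationError(f"matrix must be >= 32, got {self.matrix}")
        if self.n_slices < 4:
            raise ConfigurationError(f"n_slices must be >= 4, got {self.n_slices}")
        for key in ("air", "soft", "bone", "tooth"):
            if key not in self.tissue_hu:
                raise ConfigurationError(f"tissue_hu missing {key!r}")
        by, bx = self.body_halfaxes_mm
        ay, ax = self.arch_halfaxes_mm
        if bx >= self.fov_mm / 2 or by >= self.fov_mm / 2:
            raise ConfigurationError("body does not fit inside the field of view")
        if ax + self.tooth_radius_mm >= bx or self.arch_center_y_mm + ay + self.tooth_radius_mm >= by:
            raise ConfigurationError("dental arch (plus tooth radius) does not fit inside the body")

    @property
    def spacing(self) -> Tuple[float, float, float]:
        pix = self.fov_mm / self.matrix
        return (float(self.slice_thickness_mm), pix, pix)


@dataclasses.dataclass
class ToothSite:
    """One tooth: an ellipsoid on the dental arch."""

    center_mm: Tuple[float, float, float]  # (z, y, x)
    radius_mm: float
    z_half_extent_mm: float
    mask: VoxelMask


@dataclasses.dataclass
class DentalArch:
    """The 16 tooth sites of one case plus its filling-scheme bookkeeping."""

    teeth: List[ToothSite]
    filling_scheme: Dict[str, List[int]] = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.teeth)


def _grid_mm(cfg: PhantomConfig):
    nz, n = cfg.n_slices, cfg.matrix
    dz, dy, dx = cfg.spacing
    z = (np.arange(nz) - (nz - 1) / 2) * dz
    y = (np.arange(n) - (n - 1) / 2) * dy
    x = (np.arange(n) - (n - 1) / 2) * dx
    return z[:, None, None], y[None, :, None], x[None, None, :]


def _superellipsoid(z, y, x, center, radii, exponent=2.0):
    cz, cy, cx = center
    rz, ry, rx = radii
    t = (
        np.abs((z - cz) / rz) ** exponent
        + np.abs((y - cy) / ry) ** exponent
        + np.abs((x - cx) / rx) ** exponent
    )
    return t <= 1.0


def generate_phantom(config: PhantomConfig):
    """Generate one artifact-free case.

    Returns ``(volume, masks)`` where ``masks`` holds per-tooth masks under
    ``"teeth"`` (list of 16), plus ``"body"``, ``"ctv"``, ``"spinal_cord"``
    and ``"parotid"``.  The body mask is the tissue region (outer body
    contour minus the oral air cavity) — the region where artifact
    correction may act.
    """
    vol, masks, _arch = generate_phantom_with_arch(config)
    return vol, masks


def generate_phantom_with_arch(config: PhantomConfig):
    """As :func:`generate_phantom` but also returns the :class:`DentalArch`."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nz, n = cfg.n_slices, cfg.matrix
    dz, dy, dx = cfg.spacing
    z, y, x = _grid_mm(cfg)
    origin = (float(z[0, 0, 0]), float(y[0, 0, 0]), float(x[0, 0, 0]))
    hu = cfg.tissue_hu

    # per-case anatomical jitter (drawn in fixed order for determinism)
    body_y = cfg.body_halfaxes_mm[0] + rng.uniform(-4.0, 4.0)
    body_x = cfg.body_halfaxes_mm[1] + rng.uniform(-4.0, 4.0)
    arch_y = cfg.arch_halfaxes_mm[0] + rng.uniform(-1.5, 1.5)
    arch_x = cfg.arch_halfaxes_mm[1] + rng.uniform(-1.5, 1.5)
    arch_cy = cfg.arch_center_y_mm + rng.uniform(-2.0, 2.0)
    tooth_r = cfg.tooth_radius_mm + rng.uniform(-0.2, 0.2)
    ctv_scale = rng.uniform(1.03, 1.20)
    ctv_cy = 8.0 + rng.uniform(-5.0, 5.0)
    ctv_cz = rng.uniform(-4.0, 4.0)
    tooth_jitter = rng.uniform(-0.4, 0.4, size=(N_TEETH, 2))

    if arch_x + tooth_r >= body_x or arch_cy + arch_y + tooth_r >= body_y:
        raise ConfigurationError("jittered dental arch does not fit inside the body")

    body_outer = ((y / body_y) ** 2 + (x / body_x) ** 2) <= 1.0
    body_outer = np.broadcast_to(body_outer, (nz, n, n)).copy()

    # dental band: teeth span 3-8 slices centred on the volume midplane
    n_dental = int(np.clip(round(7.0 / dz), 3, 8))
    tooth_hz = n_dental * dz / 2.0

    # oral air cavity inside the arch, slightly taller than the teeth
    cavity = _superellipsoid(z, y, x, (0.0, arch_cy + 8.0, 0.0), (tooth_hz + 2.0, 8.0, 22.0))
    cavity &= body_outer

    # mandible (below) and maxilla (above): U-shaped arch bone bands — the
    # posterior wedge is open so no bone crosses the tongue-base region
    r2 = (np.zeros_like(z) + ((y - arch_cy) / arch_y) ** 2 + (x / arch_x) ** 2) ** 0.5
    band = (r2 >= 0.82) & (r2 <= 1.18)
    ang = np.arctan2((y - arch_cy) / arch_y, x / arch_x) + np.zeros_like(z)
    posterior = (ang > np.deg2rad(-160.0)) & (ang < np.deg2rad(-20.0))
    jaw_z = (np.abs(z) > tooth_hz) & (np.abs(z) <= tooth_hz + 14.0)
    bone = band & ~posterior & jaw_z & body_outer

    # teeth: 16 ellipsoids spaced over the anterior 240 degrees of the arch
    phis = np.deg2rad(90.0 - 120.0 + 240.0 * np.arange(N_TEETH) / (N_TEETH - 1))
    teeth_sites: List[ToothSite] = []
    spacing = cfg.spacing
    for i, phi in enumerate(phis):
        cx_t = arch_x * np.cos(phi) + tooth_jitter[i, 0]
        cy_t = arch_cy + arch_y * np.sin(phi) + tooth_jitter[i, 1]
        m = _superellipsoid(z, y, x, (0.0, cy_t, cx_t), (tooth_hz, tooth_r, tooth_r))
        teeth_sites.append(
            ToothSite(
                center_mm=(0.0, float(cy_t), float(cx_t)),
                radius_mm=float(tooth_r),
                z_half_extent_mm=float(tooth_hz),
                mask=VoxelMask(data=m, label="teeth", spacing=spacing, origin=origin),
            )
        )

    # body ROI: full-density tissue — the partial-volume rim at air
    # interfaces is excluded so HU thresholding inside the body never
    # triggers on anatomy edges
    from scipy import ndimage as _ndi

    tissue = body_outer & ~cavity
    erode_px = int(np.ceil(4 * cfg.psf_sigma_px))
    if erode_px > 0:
        st = np.zeros((3, 3, 3), dtype=bool)
        st[1] = _ndi.generate_binary_structure(2, 1)
        body_roi = _ndi.binary_erosion(tissue, structure=st, iterations=erode_px)
    else:
        body_roi = tissue

    # CTV: seeded superellipsoid at the tongue base, posterior to the arch
    ctv_r = (17.0 * ctv_scale, 31.0 * ctv_scale, 35.0 * ctv_scale)
    ctv = _superellipsoid(z, y, x, (ctv_cz, ctv_cy, 0.0), ctv_r, exponent=2.5)
    ctv &= body_roi
    for site in teeth_sites:
        ctv &= ~site.mask.data

    cord = (((y + 62.0) / 5.0) ** 2 + (x / 5.0) ** 2 + np.zeros_like(z)) <= 1.0
    cord &= body_outer
    parotid = np.zeros((nz, n, n), dtype=bool)
    for sx in (-1.0, 1.0):
        parotid |= _superellipsoid(z, y, x, (0.0, -10.0, sx * (body_x - 18.0)), (12.0, 12.0, 9.0))
    parotid &= body_outer & ~bone

    data = np.full((nz, n, n), hu["air"], dtype=np.float64)
    data[body_outer] = hu["soft"]
    data[bone] = hu["bone"]
    data[cavity] = hu["air"]
    teeth_union = np.zeros((nz, n, n), dtype=bool)
    for site in teeth_sites:
        teeth_union |= site.mask.data
    data[teeth_union] = hu["tooth"]

    if cfg.psf_sigma_px > 0:
        # bandlimit the anatomy; air away from the body stays exactly air
        near_body = _ndi.binary_dilation(body_outer[0], iterations=max(1, int(4 * cfg.psf_sigma_px)))
        for k in range(nz):
            blurred = _ndi.gaussian_filter(data[k], cfg.psf_sigma_px)
            data[k][near_body] = blurred[near_body]

    if cfg.noise_sd_hu > 0:
        noise = rng.normal(0.0, cfg.noise_sd_hu, size=data.shape)
        data[tissue] += noise[tissue]

    vol = CTVolume(data=data, spacing=spacing, origin=origin, case_id=f"seed{cfg.seed}")
    masks = {
        "teeth": [site.mask for site in teeth_sites],
        "body": VoxelMask(data=body_roi, label="body", spacing=spacing, origin=origin),
        "ctv": VoxelMask(data=ctv, label="ctv", spacing=spacing, origin=origin),
        "spinal_cord": VoxelMask(data=cord, label="spinal_cord", spacing=spacing, origin=origin),
        "parotid": VoxelMask(data=parotid, label="parotid", spacing=spacing, origin=origin),
    }
    arch = DentalArch(teeth=teeth_sites)
    return vol, masks, arch


def _position_weights(n_teeth: int) -> np.ndarray:
    """Sampling weights over arch positions: restorations cluster in the
    posterior teeth (molars > premolars > incisors), as in caries
    epidemiology."""
    w = np.empty(n_teeth)
    for i in range(n_teeth):
        # distance from the arch midline in positions
        d = abs(i - (n_teeth - 1) / 2)
        if d >= n_teeth * 0.3125:  # molar block
            w[i] = 3.0
        elif d >= n_teeth * 0.1875:  # premolars
            w[i] = 1.5
        else:  # canines/incisors
            w[i] = 0.5
    return w


def select_fillings(arch: DentalArch, scheme: str, seed: int) -> VoxelMask:
    """Select pseudo-dental-filling teeth for the ``m4`` or ``m8`` scheme.

    The selection is seeded-random, weighted toward posterior teeth, with
    the nesting constraint m4 < m8: for a given seed the four m4 teeth are
    always the first four of the eight m8 teeth, mirroring the paired
    per-case schemes.
    """
    if scheme not in ("m4", "m8"):
        raise ValidationError(f"unknown filling scheme {scheme!r}; expected 'm4' or 'm8'")
    if len(arch) < 8:
        raise ValidationError(f"dental arch has only {len(arch)} teeth; need >= 8")
    k = 4 if scheme == "m4" else 8
    rng = np.random.default_rng(seed)
    weights = _position_weights(len(arch))
    order: List[int] = []
    avail = list(range(len(arch)))
    for _ in range(8):
        w = weights[avail]
        j = rng.choice(len(avail), p=w / w.sum())
        order.append(avail.pop(int(j)))
    idx = sorted(order[:k])
    arch.filling_scheme[scheme] = idx
    ref = arch.teeth[0].mask
    union = np.zeros(ref.shape, dtype=bool)
    for i in idx:
        union |= arch.teeth[i].mask.data
    return VoxelMask(data=union, label="metal", spacing=ref.spacing, origin=ref.origin)


def insert_metal(vol: CTVolume, filling_mask: VoxelMask, metal_hu: float = 4000.0) -> CTVolume:
    """Uniformly assign ``metal_hu`` to the filling voxels (the *Reference*)."""
    vol.require_aligned(filling_mask, "filling mask")
    out = vol.copy()
    out.data[filling_mask.data] = metal_hu
    return out
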