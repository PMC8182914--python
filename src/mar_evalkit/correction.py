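"""Correction strategies for artifact-bearing volumes.

Two built-in correctors are provided behind a common plug-in contract:

* *Water* — a deterministic surrogate for the clinical manual correction:
  artifact voxels are detected by HU thresholds inside the body and set to
  water density (1.0 g/cm3, i.e. exactly 0 HU).
* *Sinogram inpainting* — a classical sinogram-domain MAR baseline: the
  metal trace of each affected slice is replaced by 1D linear interpolation
  along the detector axis and the slice is re-reconstructed.  It exhibits
  the well-known failure mode of residual blur/secondary streaks around
  metals, and stands in for a learned MAR model in the plug-in slot.

A learned MAR model (e.g. an unpaired image-translation network) is
represented only through the :class:`MarPlugin` contract, including an
external-command adapter exchanging NIfTI files.
"""

from __future__ import annotations

import dataclasses
import logging
import subprocess
import tempfile
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np
from scipy import ndimage

from .artifact_sim import (
    FanBeamGeometry,
    Sinogram,
    fbp_reconstruct,
    forward_project,
    hu_to_mu,
    MU_WATER_PER_MM,
    _fp_kernel,
)
from .errors import PluginContractError, ValidationError
from .volume_io import CTVolume, VoxelMask, clamp_hu

logger = logging.getLogger(__name__)

DARK_THRESHOLD_HU = -200.0
BRIGHT_THRESHOLD_HU = 300.0


def detect_artifact_region(
    artifacts: CTVolume,
    body: VoxelMask,
    metal: VoxelMask,
    dark_thresh: float = DARK_THRESHOLD_HU,
    bright_thresh: float = BRIGHT_THRESHOLD_HU,
) -> VoxelMask:
    """Deterministic surrogate for manual artifact delineation.

    Selects voxels inside the body, outside the metal, on slices that
    intersect metal, whose HU falls below ``dark_thresh`` or above
    ``bright_thresh``; the selection is morphologically closed with a
    1-voxel-radius structuring element and re-restricted to the eligible
    region.  Returns the *corrected_region* mask.
    """
    artifacts.require_aligned(body, "body mask")
    artifacts.require_aligned(metal, "metal mask")
    metal_slices = metal.data.any(axis=(1, 2))
    eligible = body.data & ~metal.data
    eligible &= metal_slices[:, None, None]
    region = eligible & ((artifacts.data < dark_thresh) | (artifacts.data > bright_thresh))
    if region.any():
        structure = ndimage.generate_binary_structure(3, 1)
        region = ndimage.binary_closing(region, structure=structure)
        region &= eligible
    return VoxelMask(data=region, label="corrected_region", spacing=artifacts.spacing, origin=artifacts.origin)


def water_override(artifacts: CTVolume, region: VoxelMask) -> CTVolume:
    """Set the corrected region to water density (1.0 g/cm3 <-> 0 HU).

    All voxels outside the region are untouched; idempotent.
    """
    artifacts.require_aligned(region, "corrected region")
    out = artifacts.copy()
    out.data[region.data] = 0.0
    return out


def _inpaint_trace(sino_data: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Replace trace bins by 1D linear interpolation along the detector axis.

    Views whose trace spans the entire detector row fall back to
    interpolation along the view axis (logged).
    """
    out = sino_data.copy()
    n_views, n_bins = out.shape
    bins = np.arange(n_bins)
    full_rows = []
    for v in range(n_views):
        t = trace[v]
        if not t.any():
            continue
        if t.all():
            full_rows.append(v)
            continue
        out[v, t] = np.interp(bins[t], bins[~t], sino_data[v, ~t])
    if full_rows:
        logger.warning(
            "metal trace spans the full detector in %d view(s); falling back to view-axis interpolation",
            len(full_rows),
        )
        views = np.arange(n_views)
        good = np.ones(n_views, dtype=bool)
        good[full_rows] = False
        for b in range(n_bins):
            col = out[:, b]
            col[~good] = np.interp(views[~good], views[good], col[good], period=n_views)
            out[:, b] = col
    return out


def sinogram_inpaint_mar(
    artifacts: CTVolume,
    metal: VoxelMask,
    geom: FanBeamGeometry,
    interpolation: str = "linear",
    mu_water: float = MU_WATER_PER_MM,
) -> CTVolume:
    """Classical sinogram-inpainting MAR baseline.

    Each slice intersecting the metal mask is forward projected, its metal
    trace is linearly interpolated away along the detector axis, the slice
    is reconstructed with FBP, and the original metal voxels are pasted
    back at their input HU.  If the metal mask is entirely empty every
    slice is processed, degenerating to the pure FBP round trip (no bins
    replaced).
    """
    if interpolation != "linear":
        raise ValidationError(f"unsupported interpolation {interpolation!r}")
    artifacts.require_aligned(metal, "metal mask")
    dz, dy, dx = artifacts.spacing
    out = artifacts.data.astype(np.float64).copy()
    any_metal = metal.data.any()
    # segment the trace at ~0.5 mm of metal path: bins merely grazing a
    # filling carry mostly valid data and are better left untouched
    trace_thr = 0.5 * hu_to_mu(4000.0, mu_water)
    for z in range(artifacts.shape[0]):
        mslice = metal.data[z]
        if any_metal and not mslice.any():
            continue
        sino = forward_project(artifacts.data[z], (dy, dx), geom, mu_water, slice_index=z)
        if mslice.any():
            p_metal = _fp_kernel(
                np.ascontiguousarray(np.where(mslice, hu_to_mu(4000.0, mu_water), 0.0)),
                dx,
                dy,
                geom.source_center_mm,
                geom.view_angles,
                geom.bin_angles,
                geom.coverage_radius_mm,
                0.5 * min(dx, dy),
            )
            trace = p_metal > trace_thr
            inpainted = Sinogram(_inpaint_trace(sino.data, trace), geom, z)
        else:
            inpainted = sino
        rec = fbp_reconstruct(inpainted, artifacts.shape[1:], (dy, dx), mu_water)
        rec[mslice] = artifacts.data[z][mslice]
        out[z] = rec
    return artifacts.copy(data=clamp_hu(out))


@dataclasses.dataclass
class MarPlugin:
    """Correction plug-in contract: (Artifacts volume, optional metal mask) -> corrected volume."""

    name: str
    correct: Callable[[CTVolume, Optional[VoxelMask]], CTVolume]


def run_plugin(plugin: MarPlugin, artifacts: CTVolume, metal: Optional[VoxelMask] = None) -> CTVolume:
    """Run a plug-in and validate its output against the contract."""
    out = plugin.correct(artifacts, metal)
    if not isinstance(out, CTVolume):
        raise PluginContractError(f"plugin {plugin.name!r} did not return a CTVolume")
    if not artifacts.aligned_with(out):
        raise PluginContractError(f"plugin {plugin.name!r} returned a misaligned volume")
    if not np.isfinite(out.data).all():
        raise PluginContractError(f"plugin {plugin.name!r} returned non-finite values")
    return out


def identity_plugin() -> MarPlugin:
    return MarPlugin(name="identity", correct=lambda vol, metal: vol.copy())


def estimate_body_mask(vol: CTVolume, threshold_hu: float = -400.0) -> VoxelMask:
    """Body mask from HU thresholding: largest connected component above
    ``threshold_hu``, internal air cavities excluded."""
    fg = vol.data > threshold_hu
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return VoxelMask(data=fg, label="body", spacing=vol.spacing, origin=vol.origin)


def water_plugin(
    body: Optional[VoxelMask] = None,
    dark_thresh: float = DARK_THRESHOLD_HU,
    bright_thresh: float = BRIGHT_THRESHOLD_HU,
) -> MarPlugin:
    """The *Water* condition: artifact-region detection + water override."""

    def _correct(vol: CTVolume, metal: Optional[VoxelMask]) -> CTVolume:
        if metal is None:
            metal = VoxelMask(
                data=np.zeros(vol.shape, dtype=bool), label="metal", spacing=vol.spacing, origin=vol.origin
            )
        b = body if body is not None else estimate_body_mask(vol)
        region = detect_artifact_region(vol, b, metal, dark_thresh, bright_thresh)
        return water_override(vol, region)

    return MarPlugin(name="water", correct=_correct)


def sino_interp_plugin(geom: FanBeamGeometry, mu_water: float = MU_WATER_PER_MM) -> MarPlugin:
    """The sinogram-inpainting MAR baseline as a plug-in."""

    def _correct(vol: CTVolume, metal: Optional[VoxelMask]) -> CTVolume:
        if metal is None:
            raise PluginContractError("sino_interp plugin requires a metal mask")
        return sinogram_inpaint_mar(vol, metal, geom, mu_water=mu_water)

    return MarPlugin(name="sino_interp", correct=_correct)


def external_command_plugin(name: str, command_template: str) -> MarPlugin:
    """Adapter for an external MAR tool exchanging NIfTI files.

    ``command_template`` is formatted with ``{in}``, ``{out}`` and
    ``{metal}`` placeholders and executed with the shell; the tool must
    write an aligned corrected volume to ``{out}``.
    """
    from . import volume_io

    def _correct(vol: CTVolume, metal: Optional[VoxelMask]) -> CTVolume:
        with tempfile.TemporaryDirectory(prefix="mar-plugin-") as tmp:
            tmp = Path(tmp)
            in_path = tmp / "in.nii.gz"
            out_path = tmp / "out.nii.gz"
            metal_path = tmp / "metal.nii.gz"
            volume_io.write_volume(vol, in_path)
            if metal is not None:
                volume_io.write_mask(metal, metal_path)
            cmd = command_template.format(**{"in": in_path, "out": out_path, "metal": metal_path})
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise PluginContractError(
                    f"external plugin {name!r} failed (exit {proc.returncode}): {proc.stderr.strip()}"
                )
            if not out_path.exists():
                raise PluginContractError(f"external plugin {name!r} wrote no output volume")
            out = volume_io.read_volume(out_path)
            return CTVolume(data=out.data, spacing=vol.spacing, origin=vol.origin, case_id=vol.case_id)

    return MarPlugin(name=name, correct=_correct)


def builtin_plugins(geom: FanBeamGeometry, body: Optional[VoxelMask] = None) -> Dict[str, MarPlugin]:
    return {
        "identity": identity_plugin(),
        "water": water_plugin(body=body),
        "sino_interp": sino_interp_plugin(geom),
    }
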