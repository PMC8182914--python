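"""Artifact-region detection, water override, sinogram inpainting, plug-ins."""

import sys

import numpy as np
import pytest

from mar_evalkit.correction import (
    MarPlugin,
    detect_artifact_region,
    external_command_plugin,
    identity_plugin,
    run_plugin,
    sinogram_inpaint_mar,
    water_override,
    water_plugin,
    _inpaint_trace,
)
from mar_evalkit.artifact_sim import fbp_reconstruct, forward_project
from mar_evalkit.errors import PluginContractError
from mar_evalkit.synthetic_anatomy import generate_phantom
from mar_evalkit.volume_io import CTVolume, VoxelMask, clamp_hu

from conftest import small_geometry


def soft_tissue_phantom(shape=(4, 32, 32), hu=40.0):
    """A clean all-soft-tissue cylinder with body/metal masks."""
    data = np.full(shape, -1000.0)
    yy, xx = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    disk = (yy - shape[1] / 2) ** 2 + (xx - shape[2] / 2) ** 2 <= (shape[1] / 2 - 4) ** 2
    data[:, disk] = hu
    vol = CTVolume(data=data, spacing=(2.0, 2.0, 2.0))
    body = VoxelMask(np.broadcast_to(disk, shape).copy(), label="body", spacing=vol.spacing)
    metal = VoxelMask(np.zeros(shape, bool), label="metal", spacing=vol.spacing)
    metal.data[1, shape[1] // 2, shape[2] // 2] = True
    return vol, body, metal


class TestDetectArtifactRegion:
    def test_clean_soft_tissue_phantom_yields_empty_region(self):
        vol, body, metal = soft_tissue_phantom()
        region = detect_artifact_region(vol, body, metal, dark_thresh=-200, bright_thresh=300)
        assert region.voxel_count() == 0

    def test_single_dark_voxel_selected(self):
        vol, body, metal = soft_tissue_phantom()
        vol.data[1, 10, 16] = -500.0
        region = detect_artifact_region(vol, body, metal)
        assert region.data[1, 10, 16]
        # nothing outside the closure neighborhood of that voxel
        assert region.voxel_count() <= 7

    def test_region_restricted_to_metal_slices_and_body(self):
        vol, body, metal = soft_tissue_phantom()
        vol.data[0, 10, 16] = -500.0  # slice 0 has no metal
        vol.data[1, 0, 0] = -500.0  # outside body
        region = detect_artifact_region(vol, body, metal)
        assert region.voxel_count() == 0

    def test_count_matches_brute_force_threshold_scan(self):
        rng = np.random.default_rng(0)
        vol, body, metal = soft_tissue_phantom(shape=(4, 64, 64))
        vol.data += rng.normal(0, 220, vol.shape)  # many threshold violations
        region = detect_artifact_region(vol, body, metal)
        # independent scan: eligibility + band violation, then 6-neighbor
        # closing built from np.roll dilation/erosion
        eligible = body.data & ~metal.data
        eligible &= metal.data.any(axis=(1, 2))[:, None, None]
        raw = eligible & ((vol.data < -200) | (vol.data > 300))

        def dil(m):
            out = m.copy()
            for ax in range(3):
                out |= np.roll(m, 1, ax) | np.roll(m, -1, ax)
            return out

        def ero(m):
            out = m.copy()
            for ax in range(3):
                out &= np.roll(m, 1, ax) & np.roll(m, -1, ax)
            return out

        pad = np.pad(raw, 2)
        closed = ero(dil(pad))[2:-2, 2:-2, 2:-2]
        expected = int((closed & eligible).sum())
        assert region.voxel_count() == expected


class TestWaterOverride:
    def test_empty_region_is_identity(self):
        vol, body, metal = soft_tissue_phantom()
        region = VoxelMask(np.zeros(vol.shape, bool), label="corrected_region", spacing=vol.spacing)
        assert np.array_equal(water_override(vol, region).data, vol.data)

    def test_region_voxels_set_to_exactly_water(self):
        vol, body, metal = soft_tissue_phantom()
        region = VoxelMask(body.data & (np.random.default_rng(1).random(vol.shape) < 0.3),
                           label="corrected_region", spacing=vol.spacing)
        out = water_override(vol, region)
        assert np.all(out.data[region.data] == 0.0)
        assert np.array_equal(out.data[~region.data], vol.data[~region.data])

    def test_idempotent(self):
        vol, body, _ = soft_tissue_phantom()
        region = VoxelMask(body.data.copy(), label="corrected_region", spacing=vol.spacing)
        once = water_override(vol, region)
        assert np.array_equal(water_override(once, region).data, once.data)

    def test_never_touches_metal_voxels_via_detection(self):
        vol, body, metal = soft_tissue_phantom()
        vol.data[metal.data] = 4000.0  # bright beyond threshold, but metal
        region = detect_artifact_region(vol, body, metal)
        out = water_override(vol, region)
        assert np.all(out.data[metal.data] == 4000.0)


class TestSinogramInpainting:
    def test_single_bin_trace_linear_midpoint(self):
        sino = np.zeros((1, 5))
        sino[0] = [1.0, 2.0, 9.0, 4.0, 5.0]
        trace = np.zeros((1, 5), bool)
        trace[0, 2] = True
        out = _inpaint_trace(sino, trace)
        assert out[0, 2] == pytest.approx((2.0 + 4.0) / 2.0)
        assert np.array_equal(out[0, [0, 1, 3, 4]], sino[0, [0, 1, 3, 4]])

    def test_full_row_trace_falls_back_to_view_axis(self, caplog):
        sino = np.outer(np.sin(np.linspace(0, 2 * np.pi, 8, endpoint=False)) + 2, np.ones(5))
        trace = np.zeros((8, 5), bool)
        trace[3] = True
        with caplog.at_level("WARNING", logger="mar_evalkit.correction"):
            out = _inpaint_trace(sino, trace)
        assert np.isfinite(out).all()
        assert "view-axis" in caplog.text
        assert out[3, 0] == pytest.approx((sino[2, 0] + sino[4, 0]) / 2.0)

    def test_empty_metal_mask_is_fbp_round_trip(self, tiny_phantom_config, desk_geometry):
        vol, masks = generate_phantom(tiny_phantom_config)
        empty = masks["ctv"].copy(data=np.zeros(vol.shape, bool), label="metal")
        out = sinogram_inpaint_mar(vol, empty, desk_geometry)
        sp = vol.spacing[1:]
        for z in (0, vol.shape[0] // 2):
            rt = clamp_hu(fbp_reconstruct(forward_project(vol.data[z], sp, desk_geometry), vol.data[z].shape, sp))
            assert np.allclose(out.data[z], rt, atol=1e-9)


class TestPlugins:
    def test_identity_plugin(self, tiny_phantom_config):
        vol, _ = generate_phantom(tiny_phantom_config)
        out = run_plugin(identity_plugin(), vol)
        assert np.array_equal(out.data, vol.data)

    def test_water_plugin_is_detect_plus_override(self):
        vol, body, metal = soft_tissue_phantom()
        vol.data[1, 10, 16] = -500.0
        plugin = water_plugin(body=body)
        via_plugin = run_plugin(plugin, vol, metal)
        region = detect_artifact_region(vol, body, metal)
        direct = water_override(vol, region)
        assert np.array_equal(via_plugin.data, direct.data)

    def test_external_command_identity_round_trip(self, tiny_phantom_config):
        vol, _ = generate_phantom(tiny_phantom_config)
        plugin = external_command_plugin("copy", "cp {in} {out}")
        out = run_plugin(plugin, vol)
        # NIfTI storage rounds to integer HU within the clamp range
        assert np.allclose(out.data, np.rint(clamp_hu(vol.data)), atol=0.5)

    def test_contract_violation_reported_with_plugin_name(self, tiny_phantom_config):
        vol, _ = generate_phantom(tiny_phantom_config)
        bad = MarPlugin(
            name="shrinker",
            correct=lambda v, m: CTVolume(data=v.data[:, :-1, :], spacing=v.spacing),
        )
        with pytest.raises(PluginContractError, match="shrinker"):
            run_plugin(bad, vol)

    def test_failing_external_command_raises(self, tiny_phantom_config):
        vol, _ = generate_phantom(tiny_phantom_config)
        plugin = external_command_plugin("broken", sys.executable + " -c 'import sys; sys.exit(3)'")
        with pytest.raises(PluginContractError, match="broken"):
            run_plugin(plugin, vol)
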