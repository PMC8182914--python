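"""Shared fixtures: small phantoms, geometries, and cached pipeline runs.

The expensive multi-seed and cohort runs are session-scoped so the
mechanism/ordering/regression tests share one computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

from mar_evalkit.artifact_sim import FanBeamGeometry
from mar_evalkit.study_pipeline import StudyConfig, run_case, run_study
from mar_evalkit.synthetic_anatomy import PhantomConfig


def small_geometry(n_views: int = 60, n_bins: int = 64, coverage: float = 60.0) -> FanBeamGeometry:
    """A reduced fan for fast unit tests on small slices."""
    return FanBeamGeometry(n_views=n_views, n_bins=n_bins, coverage_radius_mm=coverage)


@pytest.fixture(scope="session")
def desk_geometry() -> FanBeamGeometry:
    """Half-sampled clinical fan: 492 views x 460 bins, 59.5 cm source."""
    return FanBeamGeometry().half_profile()


@pytest.fixture(scope="session")
def std_phantom_config() -> PhantomConfig:
    """The standard 128-matrix test phantom (16 slices, 2 mm)."""
    return PhantomConfig(matrix=128, n_slices=16, slice_thickness_mm=2.0, seed=3)


@pytest.fixture(scope="session")
def tiny_phantom_config() -> PhantomConfig:
    return PhantomConfig(matrix=64, n_slices=8, slice_thickness_mm=2.0, seed=1)


def std_study_config(**overrides) -> StudyConfig:
    kw = dict(
        phantom=PhantomConfig(matrix=128, n_slices=16, slice_thickness_mm=2.0),
        write_volumes=False,
    )
    kw.update(overrides)
    return StudyConfig(**kw)


@pytest.fixture(scope="session")
def five_seed_case_metrics():
    """Five independent cases (seeds) of the standard 128-matrix fixture.

    Returns a list of dicts keyed by (scheme, condition) -> MetricRecord,
    plus per-scheme dental/non-dental variance of the artifact difference
    image (computed inside the pipeline run below).
    """
    from mar_evalkit.study_pipeline import _case_seeds
    from mar_evalkit.synthetic_anatomy import generate_phantom_with_arch, insert_metal, select_fillings
    from mar_evalkit.artifact_sim import simulate_artifact_volume
    from mar_evalkit.correction import detect_artifact_region, sinogram_inpaint_mar, water_override
    from mar_evalkit.geometry_eval import evaluate_condition, expand_margin

    cfg = std_study_config()
    out = []
    for ci in range(5):
        seeds = _case_seeds(cfg.master_seed, ci)
        pcfg = dataclasses.replace(cfg.phantom, seed=seeds["phantom"])
        if cfg.vary_fov:
            fov = float(np.random.default_rng(seeds["fov"]).uniform(350.0, 400.0))
            pcfg = dataclasses.replace(pcfg, fov_mm=fov)
        vol, masks, arch = generate_phantom_with_arch(pcfg)
        ptv = expand_margin(masks["ctv"], cfg.ptv_margin_mm)
        entry = {"records": {}, "variance": {}}
        for scheme in ("m4", "m8"):
            filling = select_fillings(arch, scheme, seeds["fillings"])
            ref = insert_metal(vol, filling, cfg.metal_hu)
            model = dataclasses.replace(cfg.corruption, seed=seeds[f"corrupt_{scheme}"])
            artifacts = simulate_artifact_volume(ref, filling, cfg.geometry, model)
            region = detect_artifact_region(artifacts, masks["body"], filling)
            water = water_override(artifacts, region)
            mar = sinogram_inpaint_mar(artifacts, filling, cfg.geometry)
            for condition, test in (("artifacts", artifacts), ("water", water), ("mar", mar)):
                entry["records"][(scheme, condition)] = evaluate_condition(
                    ref, test, ptv, region, f"case{ci}", scheme, condition
                )
            diff = artifacts.data - ref.data
            dental = filling.data.any(axis=(1, 2))
            entry["variance"][scheme] = (
                float(diff[dental].var()),
                float(diff[~dental].var()),
            )
        out.append(entry)
    return out


@pytest.fixture(scope="session")
def cohort_result(tmp_path_factory):
    """The 13-case synthetic cohort at the standard test profile."""
    cfg = std_study_config(n_cases=13, master_seed=0)
    outdir = tmp_path_factory.mktemp("cohort")
    return run_study(cfg, output_dir=str(outdir))
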