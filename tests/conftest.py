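"""Shared fixtures: tiny/small phantoms, surrogate-strain datasets, FE runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mechanoct as mc


def tiny_spec(**overrides) -> mc.PhantomSpec:
    defaults = dict(
        grid_shape=(20, 20, 20),
        cortex_outer_radius=8.0,
        cortex_inner_radius=5.5,
        defect_height=4,
        n_timepoints=3,
        noise_sd=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return mc.PhantomSpec(**defaults)


@pytest.fixture
def spec_tiny() -> mc.PhantomSpec:
    return tiny_spec()


@pytest.fixture
def baseline_tiny(spec_tiny) -> mc.DensityImage:
    return mc.make_baseline_phantom(spec_tiny)


@pytest.fixture
def masks_tiny(baseline_tiny) -> mc.RegionMasks:
    return mc.make_region_masks(baseline_tiny)


def analysis_tables(
    images: list[mc.DensityImage],
    masks: mc.RegionMasks,
    provider,
    *,
    prefilter: bool = False,
) -> pd.DataFrame:
    """Surface event tables for every interval of a simulated series.

    With ``prefilter`` off, classification runs on the raw binned images,
    which on noise-free phantoms reproduces the ground truth exactly.
    """
    bands = mc.DensityBands()
    tables = []
    for t in range(len(images) - 1):
        prev_img = mc.gaussian_prefilter(images[t]) if prefilter else images[t]
        curr_img = mc.gaussian_prefilter(images[t + 1]) if prefilter else images[t + 1]
        prev = mc.bin_to_bands(prev_img, bands)
        curr = mc.bin_to_bands(curr_img, bands)
        rm = mc.classify_remodeling(prev, curr)
        rm.interval = (t, t + 1)
        strain = provider(images[t])
        tables.append(
            mc.build_event_table(strain, rm, masks, prev, interval=(t, t + 1))
        )
    return pd.concat(tables, ignore_index=True)


@pytest.fixture(scope="session")
def surrogate_dataset():
    """Noise-free mid-size phantom driven by the surrogate strain field.

    Large enough (>5,000 surface rows pooled over intervals) for the
    parameter-recovery and calibration statistics, cheap enough to build
    once per session.
    """
    spec = mc.PhantomSpec(
        grid_shape=(30, 30, 40),
        cortex_outer_radius=12.0,
        cortex_inner_radius=8.0,
        defect_height=6,
        n_timepoints=4,
        noise_sd=0.0,
        seed=29,
    )
    provider = mc.surrogate_strain_provider()
    images, log = mc.simulate_healing(spec, provider)
    masks = mc.make_region_masks(images[0])
    table = analysis_tables(images, masks, provider)
    return dict(spec=spec, images=images, log=log, masks=masks, table=table)


@pytest.fixture(scope="session")
def small_fe_run(tmp_path_factory):
    """The full FE-driven pipeline on the small (40 x 40 x 60) phantom.

    One run shared by the acceptance-level statistics tests: the phantom
    is simulated for 3 weekly time points with the logistic mechanostat,
    strain is re-solved from the emitted images, and the pooled surface
    event table with its ground truth is returned.
    """
    out = tmp_path_factory.mktemp("small_run")
    spec = mc.PhantomSpec(n_timepoints=3, seed=7)
    cfg = mc.PipelineConfig(output_dir=str(out), phantom=spec, seed=7)
    manifest = mc.run_subject(cfg)
    events = pd.read_csv(out / "surface_events.csv")
    log = mc.GroundTruthLog.from_json(out / "ground_truth.json")
    return dict(cfg=cfg, manifest=manifest, events=events, log=log, out=out)
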