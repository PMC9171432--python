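"""End-to-end per-subject analysis: filter -> bin -> mask -> FE -> events -> stats.

A `PipelineConfig` fully determines one run: either a list of registered
density images on disk or a phantom specification, the density bands, the
filter and FE parameters, the per-time-point load schedule and the
statistics settings.  `run_subject` executes the stages, persists every
intermediate (strain fields as NIfTI, tables as CSV, CCR matrices as
HDF5) and returns a `RunManifest` describing the run.

The default load schedules encode the study protocol: loaded subjects
ramp the machine force from 8 to 16 N with a 10 mm lever arm providing
the superposed bending moment, controls carry a uniaxial 10 N load at
every time point.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .images import (
    BandedImage,
    DensityBands,
    DensityImage,
    RegionMasks,
    bin_to_bands,
    bone_volume_by_threshold,
    gaussian_prefilter,
    load_density_image,
    make_region_masks,
    save_density_image,
)
from .mechstats import MechanoregulationModel, build_event_table, per_band_summary
from .microfe import (
    FESolution,
    LoadCase,
    MaterialMap,
    ModulusRamp,
    StrainField,
    build_material_map,
    scale_strain,
    solve_axial,
    solve_bending,
    superpose,
)
from .phantom import GroundTruthLog, MechanostatRule, PhantomSpec, simulate_healing
from .remodeling import classify_remodeling, remodeling_rates

logger = logging.getLogger("mechanoct")

__all__ = [
    "TimepointLoad",
    "PipelineConfig",
    "RunManifest",
    "run_subject",
    "generate_fixture",
    "compute_interval_strain",
    "loaded_protocol",
    "control_protocol",
]


@dataclass
class TimepointLoad:
    """Applied load at one time point.

    ``machine_force_N`` of None means no bending component (control
    subjects); otherwise the applied bending moment is machine force
    times the lever arm.
    """

    axial_force_N: float = 10.0
    machine_force_N: Optional[float] = None
    moment_arm_mm: float = 10.0


def loaded_protocol(n_timepoints: int, f_start: float = 8.0, f_end: float = 16.0) -> list[TimepointLoad]:
    """Machine force ramping linearly from 8 to 16 N across time points."""
    forces = np.linspace(f_start, f_end, n_timepoints)
    return [TimepointLoad(axial_force_N=float(f), machine_force_N=float(f)) for f in forces]


def control_protocol(n_timepoints: int, force: float = 10.0) -> list[TimepointLoad]:
    """Uniaxial 10 N at every time point, no bending."""
    return [TimepointLoad(axial_force_N=force, machine_force_N=None) for _ in range(n_timepoints)]


@dataclass
class PipelineConfig:
    """Complete description of one per-subject analysis run."""

    output_dir: str = "mechanoct_run"
    subject: str = "phantom"
    image_paths: Optional[list[str]] = None  # registered series; else phantom
    phantom: Optional[PhantomSpec] = None
    band_edges: tuple[float, ...] = tuple(float(v) for v in range(395, 721, 25))
    filter_sigma: float = 1.2
    filter_support: int = 1
    cortex_threshold: float = 645.0
    poisson_ratio: float = 0.3
    ramp: ModulusRamp = field(default_factory=ModulusRamp)
    soft_tissue_modulus: float = 0.003
    plate_modulus: float = 20.0
    plate_thickness: int = 2
    fe_rtol: float = 1e-6
    loads: Optional[list[TimepointLoad]] = None  # default: loaded protocol
    n_bins: int = 50
    n_grid: int = 100
    seed: int = 0

    def resolved_loads(self, n_timepoints: int) -> list[TimepointLoad]:
        if self.loads is None:
            return loaded_protocol(n_timepoints)
        if len(self.loads) < n_timepoints:
            raise ValueError(
                f"load schedule covers {len(self.loads)} time points, need {n_timepoints}"
            )
        return list(self.loads[:n_timepoints])

    def validate(self) -> None:
        if self.image_paths is None and self.phantom is None:
            raise ValueError("config needs either image_paths or a phantom spec")
        if self.image_paths is not None:
            missing = [p for p in self.image_paths if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"missing input images: {missing}")
        n = (
            self.phantom.n_timepoints
            if self.phantom is not None
            else len(self.image_paths or [])
        )
        self.resolved_loads(n)  # raises if the schedule is too short

    def _as_dict(self) -> dict:
        data = {
            k: getattr(self, k)
            for k in (
                "output_dir", "subject", "image_paths", "band_edges",
                "filter_sigma", "filter_support", "cortex_threshold",
                "poisson_ratio", "soft_tissue_modulus", "plate_modulus",
                "plate_thickness", "fe_rtol", "n_bins", "n_grid", "seed",
            )
        }
        data["band_edges"] = list(self.band_edges)
        data["ramp"] = dataclasses.asdict(self.ramp)
        if self.loads is not None:
            data["loads"] = [dataclasses.asdict(l) for l in self.loads]
        if self.phantom is not None:
            ph = {
                k: getattr(self.phantom, k)
                for k in (
                    "grid_shape", "voxel_size_um", "cortex_outer_radius",
                    "cortex_inner_radius", "defect_height", "n_timepoints",
                    "noise_sd", "seed", "cortex_density", "soft_density",
                )
            }
            ph["grid_shape"] = list(self.phantom.grid_shape)
            ph["mechanostat"] = self.phantom.mechanostat.params or {"kind": "custom"}
            data["phantom"] = ph
        return data

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self._as_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "ramp" in data:
            data["ramp"] = ModulusRamp(**data["ramp"])
        if "loads" in data and data["loads"] is not None:
            data["loads"] = [TimepointLoad(**l) for l in data["loads"]]
        if "band_edges" in data:
            data["band_edges"] = tuple(data["band_edges"])
        if "phantom" in data and data["phantom"] is not None:
            ph = data["phantom"]
            mech = ph.pop("mechanostat", {"kind": "logistic"})
            kind = mech.pop("kind", "logistic")
            rule = (
                MechanostatRule.logistic(**mech)
                if kind == "logistic"
                else MechanostatRule.frozen()
            )
            ph["grid_shape"] = tuple(ph["grid_shape"])
            data["phantom"] = PhantomSpec(mechanostat=rule, **ph)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self._as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one pipeline run: provenance, diagnostics, outputs."""

    config_hash: str
    version: str
    subject: str
    stage_seconds: dict = field(default_factory=dict)
    solves: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    n_timepoints: int = 0
    complete: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _log_solve(manifest: Optional[RunManifest], sol: FESolution, label: str) -> None:
    rec = dict(
        label=label, mode=sol.mode, resultant=sol.resultant,
        iterations=sol.iterations, residual=sol.residual,
        seconds=round(sol.solve_seconds, 3),
    )
    logger.info(
        "FE solve %s: mode=%s resultant=%.4g iters=%d residual=%.2e (%.1fs)",
        label, sol.mode, sol.resultant, sol.iterations, sol.residual, sol.solve_seconds,
    )
    if manifest is not None:
        manifest.solves.append(rec)


def compute_interval_strain(
    img: DensityImage,
    masks: RegionMasks,
    cfg: PipelineConfig,
    load: TimepointLoad,
    manifest: Optional[RunManifest] = None,
    label: str = "",
) -> tuple[StrainField, MaterialMap]:
    """Scaled (and, if loaded, superposed) strain field for one time point."""
    bands = DensityBands(cfg.band_edges)
    filt = gaussian_prefilter(img, cfg.filter_sigma, cfg.filter_support)
    banded = bin_to_bands(filt, bands)
    mat = build_material_map(
        banded, bands, cfg.ramp,
        poisson_ratio=cfg.poisson_ratio,
        soft_tissue_modulus=cfg.soft_tissue_modulus,
        plate_modulus=cfg.plate_modulus,
        masks=masks,
        plate_thickness=cfg.plate_thickness,
        density=filt,
    )
    axial = solve_axial(mat, rtol=cfg.fe_rtol)
    _log_solve(manifest, axial, f"{label}/axial")
    axial_scaled = scale_strain(axial, load.axial_force_N)
    if load.machine_force_N is not None:
        bending = solve_bending(
            mat, LoadCase(mode="bending", machine_force_N=load.machine_force_N,
                          moment_arm_mm=load.moment_arm_mm),
            rtol=cfg.fe_rtol,
        )
        _log_solve(manifest, bending, f"{label}/bending")
        moment = load.machine_force_N * load.moment_arm_mm
        bending_scaled = scale_strain(bending, moment)
        strain = superpose(axial_scaled, bending_scaled)
    else:
        strain = axial_scaled.to_strain_field()
    return strain, mat


def _fe_strain_provider(
    masks: RegionMasks, cfg: PipelineConfig, load: TimepointLoad
) -> Callable[[DensityImage], StrainField]:
    def provider(img: DensityImage) -> StrainField:
        strain, _ = compute_interval_strain(img, masks, cfg, load)
        return strain

    return provider


def _load_or_generate_series(
    cfg: PipelineConfig, out: Path, manifest: RunManifest
) -> tuple[list[DensityImage], Optional[GroundTruthLog], RegionMasks]:
    if cfg.image_paths is not None:
        images = [load_density_image(p) for p in cfg.image_paths]
        masks = make_region_masks(images[0], cfg.cortex_threshold)
        return images, None, masks
    spec = cfg.phantom
    assert spec is not None
    from .phantom import make_baseline_phantom

    baseline = make_baseline_phantom(spec)
    masks = make_region_masks(baseline, cfg.cortex_threshold)
    loads = cfg.resolved_loads(spec.n_timepoints)

    # the generating strain provider tracks the evolving state with the
    # load scheduled for that week
    step_counter = {"t": 0}

    def provider(img: DensityImage) -> StrainField:
        t = step_counter["t"]
        step_counter["t"] += 1
        strain, _ = compute_interval_strain(
            img, masks, cfg, loads[t], manifest, label=f"gen/t{t}"
        )
        return strain

    images, log = simulate_healing(spec, provider)
    log.to_json(out / "ground_truth.json")
    manifest.outputs.append("ground_truth.json")
    return images, log, masks


def run_subject(cfg: PipelineConfig) -> RunManifest:
    """Execute the full analysis for one subject and persist all outputs."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=cfg.config_hash(), version=__version__, subject=cfg.subject
    )
    bands = DensityBands(cfg.band_edges)
    stage_t0 = time.perf_counter()

    try:
        images, log, masks = _load_or_generate_series(cfg, out, manifest)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"stage 'input' failed: {exc}") from exc
    manifest.n_timepoints = len(images)
    manifest.stage_seconds["input"] = round(time.perf_counter() - stage_t0, 3)

    loads = cfg.resolved_loads(len(images))
    cfg.to_yaml(out / "config.yaml")
    manifest.outputs.append("config.yaml")

    # stage: preprocessing (filter + bin) for every time point
    stage_t0 = time.perf_counter()
    banded: list[BandedImage] = []
    for t, img in enumerate(images):
        filt = gaussian_prefilter(img, cfg.filter_sigma, cfg.filter_support)
        banded.append(bin_to_bands(filt, bands))
    manifest.stage_seconds["preprocess"] = round(time.perf_counter() - stage_t0, 3)

    # stage: bone volume tables
    stage_t0 = time.perf_counter()
    vol_rows = []
    for t, img in enumerate(images):
        filt = gaussian_prefilter(img, cfg.filter_sigma, cfg.filter_support)
        for region in ("cortical", "medullary", "peripheral", "all"):
            df = bone_volume_by_threshold(filt, bands, masks, region)
            df.insert(0, "timepoint", t)
            df.insert(0, "subject", cfg.subject)
            vol_rows.append(df)
    volumes = pd.concat(vol_rows, ignore_index=True)
    volumes.to_csv(out / "bone_volumes.csv", index=False)
    manifest.outputs.append("bone_volumes.csv")
    manifest.stage_seconds["bone_volume"] = round(time.perf_counter() - stage_t0, 3)

    # stage: per-time-point FE (every scan, incl. the last for the strain
    # trajectory), per-interval remodeling classification and event tables
    stage_t0 = time.perf_counter()
    tables = []
    maps = []
    strains: list[StrainField] = []
    mats: list[MaterialMap] = []
    for t in range(len(images)):
        strain, mat = compute_interval_strain(
            images[t], masks, cfg, loads[t], manifest, label=f"analysis/t{t}"
        )
        strains.append(strain)
        mats.append(mat)
        save_density_image(
            DensityImage(strain.effective_strain, images[t].spacing_um),
            out / f"effective_strain_t{t}.nii.gz",
        )
        manifest.outputs.append(f"effective_strain_t{t}.nii.gz")
    strain_rows = []
    for t, strain in enumerate(strains):
        eff = np.asarray(strain.effective_strain)
        for band in range(1, bands.n_bands + 1):
            sel = np.asarray(banded[t].band_index) == band
            strain_rows.append(
                {
                    "subject": cfg.subject,
                    "timepoint": t,
                    "band": band,
                    "mean_effective_strain": float(eff[sel].mean()) if sel.any() else np.nan,
                    "n_voxels": int(sel.sum()),
                }
            )
    pd.DataFrame(strain_rows).to_csv(out / "strain_by_band.csv", index=False)
    manifest.outputs.append("strain_by_band.csv")
    for t in range(len(images) - 1):
        strain, mat = strains[t], mats[t]
        rm = classify_remodeling(banded[t], banded[t + 1])
        rm.interval = (t, t + 1)
        maps.append(rm)
        save_density_image(
            DensityImage(rm.state.astype(float), images[t].spacing_um),
            out / f"remodeling_t{t}_t{t + 1}.nii.gz",
        )
        manifest.outputs.append(f"remodeling_t{t}_t{t + 1}.nii.gz")
        table = build_event_table(
            strain, rm, masks, banded[t],
            exclude=mat.plate_mask,
            interval=(t, t + 1),
            subject=cfg.subject,
        )
        tables.append(table)
    events = pd.concat(tables, ignore_index=True)
    events.to_csv(out / "surface_events.csv", index=False)
    manifest.outputs.append("surface_events.csv")
    manifest.stage_seconds["fe_and_events"] = round(time.perf_counter() - stage_t0, 3)

    # stage: remodeling rates
    stage_t0 = time.perf_counter()
    rates = remodeling_rates(maps, images[0].voxel_volume_mm3, 1.0, bands, masks)
    rates.insert(0, "subject", cfg.subject)
    rates.to_csv(out / "remodeling_rates.csv", index=False)
    manifest.outputs.append("remodeling_rates.csv")
    manifest.stage_seconds["rates"] = round(time.perf_counter() - stage_t0, 3)

    # stage: mechano-regulation statistics (pooled + per band/region)
    stage_t0 = time.perf_counter()
    results = MechanoregulationModel(events, cfg.n_bins, cfg.n_grid).fit()
    (out / "summary.txt").write_text(results.summary() + "\n")
    manifest.outputs.append("summary.txt")
    results.prob_curve.as_frame().to_csv(out / "conditional_probability.csv", index=False)
    manifest.outputs.append("conditional_probability.csv")
    summary = per_band_summary(events, bands.n_bands, n_grid=cfg.n_grid)
    summary.to_csv(out / "per_band_summary.csv", index=False)
    manifest.outputs.append("per_band_summary.csv")
    with h5py.File(out / "ccr.h5", "w") as h5:
        if results.ccr is not None:
            h5.create_dataset("grid", data=results.ccr.grid)
            h5.create_dataset("ccr", data=results.ccr.ccr)
            h5.attrs["max_ccr"] = results.ccr.max_ccr
            h5.attrs["argmax_low"], h5.attrs["argmax_high"] = results.ccr.argmax
        if results.auc_formation is not None:
            h5.attrs["auc_formation"] = results.auc_formation.auc
        if results.auc_mineralization is not None:
            h5.attrs["auc_mineralization"] = results.auc_mineralization.auc
    manifest.outputs.append("ccr.h5")
    manifest.stage_seconds["statistics"] = round(time.perf_counter() - stage_t0, 3)

    manifest.complete = True
    manifest.to_json(out / "manifest.json")
    return manifest


def generate_fixture(
    size: str = "tiny", out_dir: str | Path = "fixture", seed: int = 0
) -> Path:
    """Write a phantom dataset (image series, ground truth, spec) to disk.

    ``tiny`` is a 20^3 grid over 3 time points that runs end to end in
    seconds; ``small`` is 40 x 40 x 60 over 3 time points (minutes) and
    yields well over 5,000 surface-event rows pooled over intervals.
    """
    presets = {
        "tiny": PhantomSpec(
            grid_shape=(20, 20, 20), cortex_outer_radius=8.0,
            cortex_inner_radius=5.5, defect_height=4, n_timepoints=3, seed=seed,
        ),
        "small": PhantomSpec(
            grid_shape=(40, 40, 60), cortex_outer_radius=16.0,
            cortex_inner_radius=11.0, defect_height=8, n_timepoints=3, seed=seed,
        ),
    }
    if size not in presets:
        raise ValueError(f"unknown fixture size {size!r}; expected tiny or small")
    spec = presets[size]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .phantom import make_baseline_phantom

    baseline = make_baseline_phantom(spec)
    masks = make_region_masks(baseline)
    cfg = PipelineConfig(output_dir=str(out), phantom=spec, seed=seed)
    loads = cfg.resolved_loads(spec.n_timepoints)
    counter = {"t": 0}

    def provider(img: DensityImage) -> StrainField:
        t = counter["t"]
        counter["t"] += 1
        strain, _ = compute_interval_strain(img, masks, cfg, loads[t])
        return strain

    images, log = simulate_healing(spec, provider)
    paths = []
    for t, img in enumerate(images):
        p = out / f"density_t{t}.nii.gz"
        save_density_image(img, p)
        paths.append(str(p))
    log.to_json(out / "ground_truth.json")
    spec.to_yaml(out / "phantom.yaml")
    cfg.image_paths = paths
    cfg.phantom = None
    cfg.to_yaml(out / "config.yaml")
    return out
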