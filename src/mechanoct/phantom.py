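"""Synthetic longitudinal phantom of a healing femoral defect.

The phantom emulates the imaging experiment the pipeline targets: a
hollow-cylinder cortical diaphysis (density above the 645 mg HA/cm^3
cortical threshold) interrupted by a fully transverse osteotomy gap, scanned
weekly as a callus forms, mineralizes and is resorbed.  Remodeling events
are sampled from a known mechanostat -- formation probability monotone
non-decreasing and resorption probability monotone non-increasing in the
local normalized effective strain -- so every downstream stage can be
validated against an exact ground-truth event log.

Remodeling acts on surfaces: soft-tissue voxels face-adjacent to bone may
form new bone (appearing at the lowest analysis density, 395 mg HA/cm^3),
bone voxels exposed to non-bone may be resorbed, and surviving bone
mineralizes by a fixed density step per week up to the cortical maximum.
Additive Gaussian noise (clipped at zero) is applied only to the emitted
images; the internal state and the event log stay noise-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import yaml

from .images import DensityImage
from .microfe import StrainField
from .remodeling import surface_candidates

__all__ = [
    "MechanostatRule",
    "PhantomSpec",
    "StepRecord",
    "GroundTruthLog",
    "make_baseline_phantom",
    "simulate_healing",
    "surrogate_strain_provider",
]

#: Density of newly formed bone: the lowest analysis band edge, mg HA/cm^3.
NEW_BONE_DENSITY = 395.0
#: Mineralization ceiling: the highest analysis band edge, mg HA/cm^3.
MAX_BONE_DENSITY = 720.0


def _logistic(x: np.ndarray, pmax: float, slope: float, mid: float) -> np.ndarray:
    return pmax / (1.0 + np.exp(-slope * (np.asarray(x, dtype=float) - mid)))


@dataclass(frozen=True)
class MechanostatRule:
    """Event-probability law of the phantom.

    ``p_form`` maps normalized effective strain in [0, 1] to the weekly
    probability that an eligible soft-tissue surface voxel forms bone
    (monotone non-decreasing); ``p_res`` maps it to the probability that an
    eligible bone surface voxel is resorbed (monotone non-increasing).
    Surviving bone gains ``mineralization_step`` mg HA/cm^3 per week.
    """

    p_form: Callable[[np.ndarray], np.ndarray]
    p_res: Callable[[np.ndarray], np.ndarray]
    mineralization_step: float = 25.0
    params: Optional[dict] = None

    def validate(self, grid: Optional[np.ndarray] = None) -> None:
        """Check 0 <= p_form, p_res and p_form + p_res <= 1 on [0, 1]."""
        grid = np.linspace(0.0, 1.0, 101) if grid is None else np.asarray(grid)
        pf = np.asarray(self.p_form(grid), dtype=float)
        pr = np.asarray(self.p_res(grid), dtype=float)
        if np.any(pf < 0) or np.any(pr < 0) or np.any(pf + pr > 1 + 1e-12):
            raise ValueError("mechanostat probabilities must satisfy 0 <= p_form + p_res <= 1")
        if np.any(np.diff(pf) < -1e-12):
            raise ValueError("p_form must be monotone non-decreasing")
        if np.any(np.diff(pr) > 1e-12):
            raise ValueError("p_res must be monotone non-increasing")

    @classmethod
    def logistic(
        cls,
        pmax_form: float = 0.6,
        slope_form: float = 10.0,
        mid_form: float = 0.3,
        pmax_res: float = 0.3,
        slope_res: float = 30.0,
        mid_res: float = 0.1,
        mineralization_step: float = 25.0,
    ) -> "MechanostatRule":
        """Smooth logistic mechanostat (the default study condition).

        Formation probability rises sigmoidally with strain towards
        ``pmax_form``; resorption probability falls from ``pmax_res``.
        """
        params = dict(
            kind="logistic",
            pmax_form=pmax_form, slope_form=slope_form, mid_form=mid_form,
            pmax_res=pmax_res, slope_res=slope_res, mid_res=mid_res,
            mineralization_step=mineralization_step,
        )
        rule = cls(
            p_form=lambda x: _logistic(x, pmax_form, slope_form, mid_form),
            p_res=lambda x: _logistic(x, pmax_res, -slope_res, mid_res),
            mineralization_step=mineralization_step,
            params=params,
        )
        rule.validate()
        return rule

    @classmethod
    def frozen(cls) -> "MechanostatRule":
        """No formation, no resorption, no mineralization."""
        zero = lambda x: np.zeros_like(np.asarray(x, dtype=float))
        return cls(p_form=zero, p_res=zero, mineralization_step=0.0,
                   params=dict(kind="frozen"))


@dataclass
class PhantomSpec:
    """Geometry, dynamics and noise of the synthetic defect phantom."""

    grid_shape: tuple[int, int, int] = (40, 40, 60)
    voxel_size_um: float = 10.5
    cortex_outer_radius: float = 16.0  # voxels
    cortex_inner_radius: float = 11.0  # voxels
    defect_height: int = 8  # voxels, fully transverse gap
    n_timepoints: int = 7
    mechanostat: MechanostatRule = field(default_factory=MechanostatRule.logistic)
    noise_sd: float = 15.0  # mg HA/cm^3
    seed: int = 0
    cortex_density: float = 720.0  # mg HA/cm^3, above the 645 cortical threshold
    soft_density: float = 120.0  # mg HA/cm^3, marrow / soft tissue

    def __post_init__(self) -> None:
        if self.cortex_inner_radius >= self.cortex_outer_radius:
            raise ValueError("cortex_inner_radius must be smaller than cortex_outer_radius")
        if not 0 <= self.defect_height <= self.grid_shape[2]:
            raise ValueError("defect_height must fit within the axial extent")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_timepoints < 2:
            raise ValueError("need at least two time points")
        if not self.soft_density < NEW_BONE_DENSITY:
            raise ValueError("soft tissue density must lie below the first band edge")

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return (self.voxel_size_um,) * 3

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: getattr(self, k)
            for k in (
                "grid_shape", "voxel_size_um", "cortex_outer_radius",
                "cortex_inner_radius", "defect_height", "n_timepoints",
                "noise_sd", "seed", "cortex_density", "soft_density",
            )
        }
        data["grid_shape"] = list(self.grid_shape)
        data["mechanostat"] = self.mechanostat.params or {"kind": "custom"}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        data = yaml.safe_load(Path(path).read_text())
        mech = data.pop("mechanostat", {"kind": "logistic"})
        kind = mech.pop("kind", "logistic")
        if kind == "logistic":
            rule = MechanostatRule.logistic(**mech)
        elif kind == "frozen":
            rule = MechanostatRule.frozen()
        else:
            raise ValueError(f"cannot reconstruct mechanostat of kind {kind!r}")
        data["grid_shape"] = tuple(data["grid_shape"])
        return cls(mechanostat=rule, **data)


def make_baseline_phantom(spec: PhantomSpec) -> DensityImage:
    """Hollow-cylinder cortex with a fully transverse zero-bone defect gap.

    Deterministic given the spec (noise applies only to simulated series).
    """
    nx, ny, nz = spec.grid_shape
    x, y = np.meshgrid(
        np.arange(nx) - nx / 2.0 + 0.5, np.arange(ny) - ny / 2.0 + 0.5, indexing="ij"
    )
    r = np.hypot(x, y)
    ring = (r <= spec.cortex_outer_radius) & (r > spec.cortex_inner_radius)
    values = np.full(spec.grid_shape, spec.soft_density)
    values[ring, :] = spec.cortex_density
    z0 = (nz - spec.defect_height) // 2
    values[:, :, z0 : z0 + spec.defect_height] = spec.soft_density
    return DensityImage(values=values, spacing_um=spec.spacing_um)


@dataclass
class StepRecord:
    """Ground truth for one weekly interval (state before -> state after)."""

    step: int
    formation_candidates: np.ndarray  # flat voxel indices
    formation_eps: np.ndarray  # true normalized effective strain at sampling
    formed: np.ndarray  # bool per candidate
    resorption_candidates: np.ndarray
    resorption_eps: np.ndarray
    resorbed: np.ndarray
    mineralized: np.ndarray  # flat indices where the density step applied


@dataclass
class GroundTruthLog:
    """Exact per-step record of every sampled remodeling event."""

    grid_shape: tuple[int, int, int]
    steps: list[StepRecord] = field(default_factory=list)

    def formation_indices(self, step: int) -> np.ndarray:
        rec = self.steps[step]
        return rec.formation_candidates[rec.formed]

    def resorption_indices(self, step: int) -> np.ndarray:
        rec = self.steps[step]
        return rec.resorption_candidates[rec.resorbed]

    def n_surface_rows(self) -> int:
        return sum(
            rec.formation_candidates.size + rec.resorption_candidates.size
            for rec in self.steps
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid_shape": list(self.grid_shape),
            "steps": [
                {
                    "step": rec.step,
                    "formation_candidates": rec.formation_candidates.tolist(),
                    "formation_eps": rec.formation_eps.tolist(),
                    "formed": rec.formed.astype(int).tolist(),
                    "resorption_candidates": rec.resorption_candidates.tolist(),
                    "resorption_eps": rec.resorption_eps.tolist(),
                    "resorbed": rec.resorbed.astype(int).tolist(),
                    "mineralized": rec.mineralized.tolist(),
                }
                for rec in self.steps
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthLog":
        payload = json.loads(Path(path).read_text())
        steps = [
            StepRecord(
                step=rec["step"],
                formation_candidates=np.asarray(rec["formation_candidates"], dtype=np.int64),
                formation_eps=np.asarray(rec["formation_eps"], dtype=float),
                formed=np.asarray(rec["formed"], dtype=bool),
                resorption_candidates=np.asarray(rec["resorption_candidates"], dtype=np.int64),
                resorption_eps=np.asarray(rec["resorption_eps"], dtype=float),
                resorbed=np.asarray(rec["resorbed"], dtype=bool),
                mineralized=np.asarray(rec["mineralized"], dtype=np.int64),
            )
            for rec in payload["steps"]
        ]
        return cls(grid_shape=tuple(payload["grid_shape"]), steps=steps)


StrainProvider = Callable[[DensityImage], StrainField]


def _normalize_strain(eps: np.ndarray) -> np.ndarray:
    p99 = np.percentile(eps, 99)
    if p99 <= 0:
        return np.zeros_like(eps)
    return eps / p99


def simulate_healing(
    spec: PhantomSpec,
    strain_provider: StrainProvider,
) -> tuple[list[DensityImage], GroundTruthLog]:
    """Simulate weekly healing driven by the mechanostat.

    At every step the strain provider is evaluated on the current
    noise-free state, effective strain is normalized to its 99th
    percentile over the whole volume, and surface events are sampled:
    formation candidates form with ``p_form(eps)``, resorption candidates
    are lost with ``p_res(eps)``, surviving bone mineralizes by the fixed
    weekly step (capped at the cortical maximum).  The emitted images add
    Gaussian noise of sd ``noise_sd`` (clipped at zero); the returned log
    records every candidate with its true normalized strain and outcome.
    """
    rule = spec.mechanostat
    rule.validate()
    seq = np.random.SeedSequence(spec.seed)
    event_rng, noise_rng = (np.random.default_rng(s) for s in seq.spawn(2))

    def emit(state: np.ndarray) -> DensityImage:
        values = state.copy()
        if spec.noise_sd > 0:
            values = values + noise_rng.normal(0.0, spec.noise_sd, size=values.shape)
            values = np.clip(values, 0.0, None)
        return DensityImage(values=values, spacing_um=spec.spacing_um)

    state = make_baseline_phantom(spec).values.copy()
    images = [emit(state)]
    log = GroundTruthLog(grid_shape=spec.grid_shape)

    for step in range(1, spec.n_timepoints):
        field_now = strain_provider(DensityImage(values=state.copy(), spacing_um=spec.spacing_um))
        ebar = _normalize_strain(np.asarray(field_now.effective_strain, dtype=float))

        bone = state >= NEW_BONE_DENSITY
        form_cand, res_cand = surface_candidates(bone)
        fc_idx = np.flatnonzero(form_cand)
        rc_idx = np.flatnonzero(res_cand)
        fc_eps = ebar.ravel()[fc_idx]
        rc_eps = ebar.ravel()[rc_idx]

        pf = np.asarray(rule.p_form(fc_eps), dtype=float)
        pr = np.asarray(rule.p_res(rc_eps), dtype=float)
        if np.any(pf < 0) or np.any(pf > 1) or np.any(pr < 0) or np.any(pr > 1):
            raise ValueError("mechanostat produced probabilities outside [0, 1]")

        formed = event_rng.random(fc_idx.size) < pf
        resorbed = event_rng.random(rc_idx.size) < pr

        flat = state.reshape(-1)
        # mineralize surviving pre-existing bone first (newly formed voxels
        # enter at 395 and only start mineralizing the following week)
        survivors = bone.reshape(-1).copy()
        survivors[rc_idx[resorbed]] = False
        mineralizable = np.flatnonzero(survivors & (flat < MAX_BONE_DENSITY))
        if rule.mineralization_step > 0:
            flat[mineralizable] = np.minimum(
                flat[mineralizable] + rule.mineralization_step, MAX_BONE_DENSITY
            )
            mineralized = mineralizable
        else:
            mineralized = np.empty(0, dtype=np.int64)
        flat[rc_idx[resorbed]] = spec.soft_density
        flat[fc_idx[formed]] = NEW_BONE_DENSITY

        log.steps.append(
            StepRecord(
                step=step,
                formation_candidates=fc_idx,
                formation_eps=fc_eps,
                formed=formed,
                resorption_candidates=rc_idx,
                resorption_eps=rc_eps,
                resorbed=resorbed,
                mineralized=mineralized,
            )
        )
        images.append(emit(state))
    return images, log


def surrogate_strain_provider(
    decay_voxels: float = 8.0, soft_boost: float = 2.0
) -> StrainProvider:
    """Cheap geometric stand-in for the micro-FE solver in fast tests.

    Effective strain decays exponentially with axial distance from the
    defect mid-plane (where deformation concentrates in a transversely cut
    diaphysis) and is higher in soft tissue than in bone, qualitatively
    mimicking the solved field at a tiny fraction of the cost.
    """

    def provider(img: DensityImage) -> StrainField:
        nz = img.shape[2]
        z = np.arange(nz, dtype=float)
        profile = np.exp(-np.abs(z - (nz - 1) / 2.0) / decay_voxels)
        eps = np.broadcast_to(profile, img.shape).copy()
        eps[img.values < NEW_BONE_DENSITY] *= soft_boost
        return StrainField(
            effective_strain=eps,
            sed=0.5 * eps**2,
            spacing_um=img.spacing_um,
        )

    return provider
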