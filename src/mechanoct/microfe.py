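"""Voxel-based linear-elastic micro-finite-element analysis.

Each image voxel becomes one 8-node hexahedral element with trilinear shape
functions and isotropic linear-elastic material behaviour.  The full voxel
block is meshed -- soft tissue included -- so the stiffness matrix is
assembled over a regular grid of identical elements whose stiffness differs
only by the per-voxel Young's modulus.  Two displacement-controlled load
cases are supported:

* **axial** -- a uniform compressive displacement of ``applied_strain_fraction``
  (default 1%) of the mesh height imposed on the top slice, with the bottom
  slice fixed in the axial direction only;
* **bending** -- a top-slice axial displacement varying linearly with the
  signed in-plane distance from a bending axis through the density-weighted
  centre of mass, reaching the full 1% of mesh height at the furthest
  in-plane edge.

Displacement solutions are rescaled to the *in vivo* load by the ratio of
the applied force (or moment) to the reaction resultant of the simulation,
and the axial and bending fields are superposed at the displacement level
before strain energy density ``U`` and effective strain ``sqrt(2 U / E)``
are evaluated per element.

Internal units: lengths mm, moduli MPa, forces N, moments N mm, SED MPa.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .images import BandedImage, DensityBands, DensityImage, RegionMasks

__all__ = [
    "MaterialMap",
    "LoadCase",
    "FESolution",
    "StrainField",
    "ModulusRamp",
    "build_material_map",
    "solve_axial",
    "solve_bending",
    "scale_strain",
    "superpose",
    "hex_stiffness",
    "elasticity_matrix",
]

# local corner offsets of the trilinear hexahedron, standard ordering
_CORNERS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)
# natural coordinates of the corners in [-1, 1]^3
_XI = 2.0 * _CORNERS - 1.0


def elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """Isotropic 6x6 elasticity matrix (engineering shear strains).

    Strain ordering: (xx, yy, zz, xy, yz, zx).
    """
    if not 0.0 <= nu < 0.5:
        raise ValueError(f"Poisson ratio must be in [0, 0.5), got {nu}")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] += 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def _shape_gradients(xi: np.ndarray, dims: tuple[float, float, float]) -> np.ndarray:
    """Gradients dN_a/dx (8 x 3) at natural point xi for a box element."""
    dx, dy, dz = dims
    g = np.empty((8, 3))
    for a in range(8):
        xa, ya, za = _XI[a]
        g[a, 0] = 0.125 * xa * (1 + ya * xi[1]) * (1 + za * xi[2]) * (2.0 / dx)
        g[a, 1] = 0.125 * ya * (1 + xa * xi[0]) * (1 + za * xi[2]) * (2.0 / dy)
        g[a, 2] = 0.125 * za * (1 + xa * xi[0]) * (1 + ya * xi[1]) * (2.0 / dz)
    return g


def _b_matrix(xi: np.ndarray, dims: tuple[float, float, float]) -> np.ndarray:
    """Strain-displacement matrix (6 x 24) at natural point xi."""
    g = _shape_gradients(xi, dims)
    B = np.zeros((6, 24))
    for a in range(8):
        c = 3 * a
        B[0, c + 0] = g[a, 0]
        B[1, c + 1] = g[a, 1]
        B[2, c + 2] = g[a, 2]
        B[3, c + 0] = g[a, 1]
        B[3, c + 1] = g[a, 0]
        B[4, c + 1] = g[a, 2]
        B[4, c + 2] = g[a, 1]
        B[5, c + 0] = g[a, 2]
        B[5, c + 2] = g[a, 0]
    return B


def hex_stiffness(nu: float, dx: float, dy: float, dz: float) -> np.ndarray:
    """Unit-modulus 24x24 stiffness of a box hexahedron (2x2x2 Gauss)."""
    C = elasticity_matrix(1.0, nu)
    dims = (dx, dy, dz)
    detJ = dx * dy * dz / 8.0
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    Ke = np.zeros((24, 24))
    for x in gp:
        for y in gp:
            for z in gp:
                B = _b_matrix(np.array([x, y, z]), dims)
                Ke += B.T @ C @ B * detJ
    return 0.5 * (Ke + Ke.T)


@dataclass
class ModulusRamp:
    """Monotone linear density-to-modulus mapping for bone voxels.

    The published density-to-modulus law of any given study can be plugged
    in by adjusting the endpoints; the default ramps linearly from 4 GPa at
    the lowest analysis density (395 mg HA/cm^3) to 15 GPa at the highest
    (720 mg HA/cm^3).
    """

    density_lo: float = 395.0
    density_hi: float = 720.0
    modulus_lo_gpa: float = 4.0
    modulus_hi_gpa: float = 15.0

    def __post_init__(self) -> None:
        if self.density_hi <= self.density_lo:
            raise ValueError("density_hi must exceed density_lo")
        if self.modulus_hi_gpa < self.modulus_lo_gpa:
            raise ValueError("modulus ramp must be non-decreasing in density")

    def __call__(self, density: np.ndarray) -> np.ndarray:
        frac = np.clip(
            (np.asarray(density, dtype=float) - self.density_lo)
            / (self.density_hi - self.density_lo),
            0.0,
            1.0,
        )
        return self.modulus_lo_gpa + frac * (self.modulus_hi_gpa - self.modulus_lo_gpa)


@dataclass
class MaterialMap:
    """Per-voxel Young's moduli (GPa) with uniform Poisson ratio.

    ``plate_mask`` marks the stiff cap plate placed over the medullary
    cavity at the top of the mesh to prevent edge artefacts from soft
    tissue on the loaded face.
    """

    youngs_modulus: np.ndarray  # (nx, ny, nz), GPa
    poisson_ratio: float = 0.3
    spacing_um: tuple[float, float, float] = (10.5, 10.5, 10.5)
    soft_tissue_modulus: float = 0.003  # GPa
    plate_modulus: float = 20.0  # GPa
    plate_mask: Optional[np.ndarray] = None
    density: Optional[np.ndarray] = None  # mg HA/cm^3, for bending-axis COM

    def __post_init__(self) -> None:
        self.youngs_modulus = np.asarray(self.youngs_modulus, dtype=float)
        if self.youngs_modulus.ndim != 3:
            raise ValueError("youngs_modulus must be a 3-D array")
        if np.any(self.youngs_modulus <= 0):
            raise ValueError("all Young's moduli must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.youngs_modulus.shape

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.asarray(self.spacing_um, dtype=float) / 1000.0


def build_material_map(
    banded: BandedImage,
    bands: DensityBands,
    ramp: ModulusRamp | None = None,
    *,
    poisson_ratio: float = 0.3,
    soft_tissue_modulus: float = 0.003,
    plate_modulus: float = 20.0,
    masks: Optional[RegionMasks] = None,
    plate_thickness: int = 2,
    density: Optional[DensityImage] = None,
) -> MaterialMap:
    """Map a banded density image to per-voxel Young's moduli.

    Non-bone voxels (band 0) receive the soft-tissue modulus; bone voxels
    are mapped through the monotone ``ramp`` evaluated at the lower edge of
    their density band.  If region ``masks`` are given, the medullary
    cavity is capped by ``plate_thickness`` slices of plate material at the
    top of the mesh.
    """
    ramp = ramp or ModulusRamp(density_lo=bands.edges[0], density_hi=bands.edges[-1])
    band = banded.band_index
    E = np.full(band.shape, float(soft_tissue_modulus))
    bone = band >= 1
    if np.any(bone):
        edge_density = np.asarray(bands.edges, dtype=float)[band[bone] - 1]
        E[bone] = ramp(edge_density)
    plate = np.zeros(band.shape, dtype=bool)
    if masks is not None and plate_thickness > 0:
        med = masks.label == RegionMasks.MEDULLARY
        med_cols = med.any(axis=2)
        plate[:, :, -plate_thickness:] = med_cols[:, :, None]
        E[plate] = float(plate_modulus)
    dens = density.values if density is not None else None
    return MaterialMap(
        youngs_modulus=E,
        poisson_ratio=poisson_ratio,
        spacing_um=tuple(banded.spacing_um),
        soft_tissue_modulus=soft_tissue_modulus,
        plate_modulus=plate_modulus,
        plate_mask=plate,
        density=dens,
    )


@dataclass
class LoadCase:
    """Displacement-controlled load case plus the in vivo load to scale to.

    ``applied_force_N`` is the compressive axial force for axial cases; for
    bending cases the applied moment is ``machine_force_N * moment_arm_mm``
    (the fixator pin length acts as the lever arm).
    """

    mode: str = "axial"  # "axial" | "bending"
    applied_strain_fraction: float = 0.01
    applied_force_N: float = 10.0
    machine_force_N: float = 10.0
    moment_arm_mm: float = 10.0
    bending_axis: str = "y"  # deflection varies along the perpendicular axis

    def __post_init__(self) -> None:
        if self.mode not in ("axial", "bending"):
            raise ValueError(f"unknown load mode {self.mode!r}")
        if self.applied_strain_fraction <= 0:
            raise ValueError("applied_strain_fraction must be positive")
        if self.moment_arm_mm <= 0:
            raise ValueError("moment_arm_mm must be positive")

    @property
    def applied_moment_Nmm(self) -> float:
        return self.machine_force_N * self.moment_arm_mm


@dataclass
class StrainField:
    """Per-voxel strain energy density (MPa) and effective strain."""

    effective_strain: np.ndarray
    sed: np.ndarray
    spacing_um: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.effective_strain.shape


@dataclass
class FESolution:
    """Result of one voxel-FE solve (or a scaled/superposed combination)."""

    displacement: np.ndarray  # (n_nodes, 3), mm
    sed: np.ndarray  # (nx, ny, nz), MPa
    effective_strain: np.ndarray  # (nx, ny, nz)
    resultant: float  # N (axial) or N mm (bending)
    mode: str
    material: MaterialMap
    scale: float = 1.0
    iterations: int = 0
    residual: float = 0.0
    solve_seconds: float = 0.0
    bending_distance: Optional[np.ndarray] = None  # signed per-node, mm

    def to_strain_field(self) -> StrainField:
        return StrainField(
            effective_strain=self.effective_strain,
            sed=self.sed,
            spacing_um=tuple(self.material.spacing_um),
        )


class ConvergenceError(RuntimeError):
    pass


def _grid_arrays(shape: tuple[int, int, int]) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Element-to-node connectivity for a full voxel grid."""
    nx, ny, nz = shape
    nodes_shape = (nx + 1, ny + 1, nz + 1)
    ex, ey, ez = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    base = np.stack([ex.ravel(), ey.ravel(), ez.ravel()], axis=1)  # (nelem, 3)
    corners = base[:, None, :] + _CORNERS[None, :, :]  # (nelem, 8, 3)
    elem_nodes = np.ravel_multi_index(
        (corners[..., 0], corners[..., 1], corners[..., 2]), nodes_shape
    ).astype(np.int64)
    return elem_nodes, nodes_shape


def _assemble(E_mpa: np.ndarray, elem_nodes: np.ndarray, Ke: np.ndarray) -> sp.csr_matrix:
    """Assemble the global stiffness as CSR, element moduli scaling Ke.

    Assembly runs in eight passes (one per local row node) to bound peak
    memory on large grids.
    """
    nelem = elem_nodes.shape[0]
    n_nodes = int(elem_nodes.max()) + 1
    ndof = 3 * n_nodes
    K = sp.csr_matrix((ndof, ndof))
    dof = (3 * elem_nodes[:, :, None] + np.arange(3)[None, None, :]).reshape(nelem, 24)
    for a in range(8):
        rows = np.repeat(dof[:, 3 * a : 3 * a + 3], 24, axis=1).reshape(-1)
        cols = np.tile(dof, (1, 3)).reshape(-1)
        vals = (E_mpa[:, None] * Ke[3 * a : 3 * a + 3, :].reshape(1, 72)).reshape(-1)
        K = K + sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


def _solve_system(
    K: sp.csr_matrix,
    fixed_dofs: np.ndarray,
    fixed_vals: np.ndarray,
    rtol: float,
    maxiter: int,
) -> tuple[np.ndarray, int, float]:
    """Solve K u = 0 subject to Dirichlet values via Jacobi-PCG."""
    ndof = K.shape[0]
    u = np.zeros(ndof)
    u[fixed_dofs] = fixed_vals
    free = np.ones(ndof, dtype=bool)
    free[fixed_dofs] = False
    free_idx = np.flatnonzero(free)
    b = -(K @ u)[free_idx]
    Kff = K[free_idx][:, free_idx].tocsr()
    diag = Kff.diagonal()
    diag[diag <= 0] = 1.0
    M = spla.LinearOperator(Kff.shape, matvec=lambda x: x / diag)
    n_iter = 0

    def _count(_):
        nonlocal n_iter
        n_iter += 1

    uf, info = spla.cg(Kff, b, rtol=rtol, atol=0.0, maxiter=maxiter, M=M, callback=_count)
    res = float(np.linalg.norm(Kff @ uf - b) / max(np.linalg.norm(b), 1e-300))
    if info != 0:
        raise ConvergenceError(
            f"PCG did not converge in {maxiter} iterations "
            f"(relative residual {res:.3e}, target {rtol:.1e})"
        )
    u[free_idx] = uf
    return u, n_iter, res


def _element_fields(
    u: np.ndarray,
    elem_nodes: np.ndarray,
    E_mpa: np.ndarray,
    nu: float,
    dims_mm: tuple[float, float, float],
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid SED (MPa) and effective strain per element."""
    B0 = _b_matrix(np.zeros(3), dims_mm)
    C1 = elasticity_matrix(1.0, nu)
    dof = (3 * elem_nodes[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    ue = u[dof]  # (nelem, 24)
    eps = ue @ B0.T  # (nelem, 6)
    sed = 0.5 * E_mpa * np.einsum("ij,jk,ik->i", eps, C1, eps)
    sed = np.maximum(sed, 0.0)
    eff = np.sqrt(2.0 * sed / E_mpa)
    return sed.reshape(shape), eff.reshape(shape)


def _top_bottom_nodes(nodes_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    nxn, nyn, nzn = nodes_shape
    ix, iy = np.meshgrid(np.arange(nxn), np.arange(nyn), indexing="ij")
    top = np.ravel_multi_index((ix, iy, np.full_like(ix, nzn - 1)), nodes_shape).ravel()
    bot = np.ravel_multi_index((ix, iy, np.zeros_like(ix)), nodes_shape).ravel()
    return top, bot


def _pin_dofs(nodes_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Minimal in-plane pins on the bottom slice to remove rigid-body modes.

    The stated axial-only constraints leave in-plane translation and
    rotation about the axial axis unconstrained; pinning ux, uy at one
    bottom corner and uy at a second corner offset in x removes them with
    the least perturbation of the stress field.
    """
    nxn, nyn, nzn = nodes_shape
    n0 = np.ravel_multi_index((0, 0, 0), nodes_shape)
    n1 = np.ravel_multi_index((nxn - 1, 0, 0), nodes_shape)
    dofs = np.array([3 * n0 + 0, 3 * n0 + 1, 3 * n1 + 1])
    return dofs, np.zeros(3)


def _run_solve(
    mat: MaterialMap,
    top_uz: np.ndarray,
    mode: str,
    rtol: float,
    maxiter: Optional[int],
) -> tuple[np.ndarray, float, int, float, float, np.ndarray, tuple[int, int, int]]:
    t0 = time.perf_counter()
    shape = mat.shape
    dims_mm = tuple(mat.spacing_mm)
    elem_nodes, nodes_shape = _grid_arrays(shape)
    E_mpa = (mat.youngs_modulus * 1000.0).ravel()
    Ke = hex_stiffness(mat.poisson_ratio, *dims_mm)
    K = _assemble(E_mpa, elem_nodes, Ke)
    top, bot = _top_bottom_nodes(nodes_shape)
    pin_dofs, pin_vals = _pin_dofs(nodes_shape)
    fixed = np.concatenate([3 * top + 2, 3 * bot + 2, pin_dofs])
    vals = np.concatenate([top_uz, np.zeros(bot.size), pin_vals])
    # pins may duplicate axial constraints only if corner nodes repeat; keep order
    fixed, unique_idx = np.unique(fixed, return_index=True)
    vals = vals[unique_idx]
    ndof = K.shape[0]
    if maxiter is None:
        maxiter = int(20 * np.sqrt(ndof))
    u, n_iter, res = _solve_system(K, fixed, vals, rtol, maxiter)
    reactions = K @ u
    seconds = time.perf_counter() - t0
    return u, reactions, n_iter, res, seconds, elem_nodes, nodes_shape


def _finish(
    mat: MaterialMap,
    u: np.ndarray,
    elem_nodes: np.ndarray,
    resultant: float,
    mode: str,
    n_iter: int,
    res: float,
    seconds: float,
    bending_distance: Optional[np.ndarray] = None,
) -> FESolution:
    E_mpa = (mat.youngs_modulus * 1000.0).ravel()
    sed, eff = _element_fields(
        u, elem_nodes, E_mpa, mat.poisson_ratio, tuple(mat.spacing_mm), mat.shape
    )
    return FESolution(
        displacement=u.reshape(-1, 3),
        sed=sed,
        effective_strain=eff,
        resultant=resultant,
        mode=mode,
        material=mat,
        iterations=n_iter,
        residual=res,
        solve_seconds=seconds,
        bending_distance=bending_distance,
    )


def solve_axial(
    mat: MaterialMap,
    load: LoadCase | None = None,
    *,
    rtol: float = 1e-6,
    maxiter: Optional[int] = None,
) -> FESolution:
    """Uniaxial compression: top slice displaced axially, bottom held.

    The top slice is displaced by ``-applied_strain_fraction`` times the
    mesh height; lateral expansion of both end slices remains free apart
    from the minimal rigid-body pins.
    """
    load = load or LoadCase(mode="axial")
    shape = mat.shape
    height = shape[2] * mat.spacing_mm[2]
    nodes_shape = (shape[0] + 1, shape[1] + 1, shape[2] + 1)
    top, _ = _top_bottom_nodes(nodes_shape)
    top_uz = np.full(top.size, -load.applied_strain_fraction * height)
    u, reactions, n_iter, res, secs, elem_nodes, _ = _run_solve(
        mat, top_uz, "axial", rtol, maxiter
    )
    F_res = float(reactions[3 * top + 2].sum())
    return _finish(mat, u, elem_nodes, F_res, "axial", n_iter, res, secs)


def _bending_distance(mat: MaterialMap, load: LoadCase) -> tuple[np.ndarray, np.ndarray]:
    """Signed in-plane node distance (mm) from the bending axis.

    The axis passes through the density-weighted in-plane centre of mass
    and runs along ``load.bending_axis``; the deflection therefore varies
    along the perpendicular in-plane direction.
    """
    shape = mat.shape
    nodes_shape = (shape[0] + 1, shape[1] + 1, shape[2] + 1)
    weight = mat.density if mat.density is not None else mat.youngs_modulus
    weight = np.asarray(weight, dtype=float)
    axis = 0 if load.bending_axis == "y" else 1  # varying coordinate
    # density-weighted centre of mass of the varying coordinate (voxel centres)
    coords = np.arange(shape[axis]) + 0.5
    w = weight.sum(axis=tuple(i for i in range(3) if i != axis))
    total = w.sum()
    com = float((coords * w).sum() / total) if total > 0 else shape[axis] / 2.0
    node_coord = np.arange(shape[axis] + 1, dtype=float)
    d_vox = node_coord - com
    d_mm = d_vox * mat.spacing_mm[axis]
    # broadcast to the full top-slice node grid
    if axis == 0:
        d2d = np.broadcast_to(d_mm[:, None], (nodes_shape[0], nodes_shape[1]))
    else:
        d2d = np.broadcast_to(d_mm[None, :], (nodes_shape[0], nodes_shape[1]))
    return d2d.ravel(), d_mm


def solve_bending(
    mat: MaterialMap,
    load: LoadCase | None = None,
    *,
    rtol: float = 1e-6,
    maxiter: Optional[int] = None,
) -> FESolution:
    """Bending: top-slice axial displacement linear in distance from the axis.

    The displacement reaches ``applied_strain_fraction`` of the mesh height
    at the furthest in-plane edge from the bending axis; the resultant is
    reported as a moment (axial reactions weighted by their signed lever
    arms about the axis).
    """
    load = load or LoadCase(mode="bending")
    shape = mat.shape
    height = shape[2] * mat.spacing_mm[2]
    nodes_shape = (shape[0] + 1, shape[1] + 1, shape[2] + 1)
    top, _ = _top_bottom_nodes(nodes_shape)
    d_nodes, d_mm = _bending_distance(mat, load)
    d_max = float(np.abs(d_mm).max())
    if d_max <= 0:
        raise ValueError("degenerate in-plane extent for bending")
    top_uz = -load.applied_strain_fraction * height * d_nodes / d_max
    u, reactions, n_iter, res, secs, elem_nodes, _ = _run_solve(
        mat, top_uz, "bending", rtol, maxiter
    )
    M_res = float((reactions[3 * top + 2] * d_nodes).sum())
    return _finish(
        mat, u, elem_nodes, M_res, "bending", n_iter, res, secs,
        bending_distance=d_nodes,
    )


def scale_strain(sol: FESolution, applied: float) -> FESolution:
    """Rescale a solution to the applied in vivo load.

    The scale factor is ``applied / resultant``; displacement and strain
    scale linearly, strain energy density quadratically.
    """
    if sol.resultant == 0:
        raise ValueError("zero reaction resultant: empty or disconnected mesh")
    s = applied / abs(sol.resultant)
    return replace(
        sol,
        displacement=sol.displacement * s,
        sed=sol.sed * s * s,
        effective_strain=sol.effective_strain * abs(s),
        resultant=sol.resultant * s,
        scale=sol.scale * s,
    )


def superpose(axial_scaled: FESolution, bending_scaled: FESolution) -> StrainField:
    """Superpose scaled axial and bending solutions at the displacement level.

    Strain tensors are recomputed from the summed displacement field, so
    SED and effective strain are those of the combined state, not sums of
    the individual scalars.
    """
    if axial_scaled.material.shape != bending_scaled.material.shape:
        raise ValueError("mesh mismatch between axial and bending solutions")
    mat = axial_scaled.material
    u = (axial_scaled.displacement + bending_scaled.displacement).ravel()
    elem_nodes, _ = _grid_arrays(mat.shape)
    E_mpa = (mat.youngs_modulus * 1000.0).ravel()
    sed, eff = _element_fields(
        u, elem_nodes, E_mpa, mat.poisson_ratio, tuple(mat.spacing_mm), mat.shape
    )
    return StrainField(
        effective_strain=eff, sed=sed, spacing_um=tuple(mat.spacing_um)
    )
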