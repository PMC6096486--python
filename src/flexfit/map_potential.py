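"""Real-space density maps as attractive potentials (the MDFF idea).

A density grid is reinterpreted as a potential energy field: each enabled
heavy atom contributes E_i = -w * rho_hat(x_i), where rho_hat is the
sigma-normalized density (rho - mean)/sigma and w is a global coupling
weight in kJ/mol per normalized-density unit.  Forces therefore point up
the density gradient, pulling atoms into local density maxima.

Interpolation is tricubic (Catmull-Rom), giving a C1 interpolant whose
gradient is returned analytically; trilinear is available as a fallback.
Atoms outside the interpolable region feel no map force.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .structure import FlexfitError, StructureModel

log = logging.getLogger("flexfit")

DEFAULT_MASK_RADIUS = 4.0  # A


class MapError(FlexfitError):
    pass


@dataclass
class DensityMap:
    """A 3-D density grid with origin/voxel metadata.

    ``values`` is indexed [ix, iy, iz]; the Cartesian position of voxel
    (i, j, k) is ``origin + (i, j, k) * voxel``.
    """
    values: np.ndarray
    origin: np.ndarray
    voxel: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel = np.asarray(self.voxel, dtype=float)
        if self.values.ndim != 3:
            raise MapError("map values must be a 3-D grid")
        if np.any(self.voxel <= 0):
            raise MapError("voxel size components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def stats(self) -> dict:
        v = self.values
        return {"min": float(v.min()), "max": float(v.max()),
                "mean": float(v.mean()), "sigma": float(v.std())}

    def voxel_centres(self) -> np.ndarray:
        """(N, 3) Cartesian coordinates of every voxel, in C order."""
        nx, ny, nz = self.shape
        ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3)
        return self.origin + idx * self.voxel

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.origin.copy(),
                          self.voxel.copy())


# ---------------------------------------------------------------------------
# MRC/CCP4 I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_map(path: str) -> DensityMap:
    """Read an MRC/CCP4 map, normalizing axis order to x,y,z.

    The origin honours a nonzero ORIGIN header; otherwise it falls back to
    the NXSTART-style start indices scaled by the voxel size.
    """
    import gemmi

    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
        # ORIGIN words must be read before setup() (which may renumber starts)
        header_origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
        nstart = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
        axis_order = [ccp4.header_i32(w) for w in (17, 18, 19)]
        ccp4.setup(float("nan"))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapError(f"cannot read map {path}: {exc}") from exc
    grid = ccp4.grid
    values = np.array(grid, copy=True, dtype=float)
    if np.any(np.isnan(values)):
        raise MapError(f"{path}: map does not cover its full cell")
    cell = grid.unit_cell
    if abs(cell.alpha - 90) > 1e-3 or abs(cell.beta - 90) > 1e-3 \
            or abs(cell.gamma - 90) > 1e-3:
        raise MapError("only orthogonal (P1, 90/90/90) map grids are supported")
    voxel = np.array([cell.a / values.shape[0], cell.b / values.shape[1],
                      cell.c / values.shape[2]])
    if np.any(voxel <= 0):
        raise MapError(f"{path}: nonpositive voxel size")
    if np.any(header_origin != 0.0):
        origin = header_origin
    else:
        # permute nstart from file (col,row,sec) order to x,y,z
        ns_xyz = np.zeros(3)
        for n, ax in zip(nstart, axis_order):
            ns_xyz[ax - 1] = n
        origin = ns_xyz * voxel
    return DensityMap(values=values, origin=origin, voxel=voxel)


def write_map(dmap: DensityMap, path: str) -> None:
    """Write a mode-2 (float32) CCP4/MRC map with an ORIGIN header."""
    import gemmi

    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    nx, ny, nz = dmap.shape
    grid.unit_cell = gemmi.UnitCell(nx * dmap.voxel[0], ny * dmap.voxel[1],
                                    nz * dmap.voxel[2], 90, 90, 90)
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)
    for w, val in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(w, float(val))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _catmull_rom_weights(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Catmull-Rom basis weights and their u-derivatives; u in [0,1), (N,)."""
    u2, u3 = u * u, u * u * u
    w = np.stack([
        0.5 * (-u3 + 2 * u2 - u),
        0.5 * (3 * u3 - 5 * u2 + 2),
        0.5 * (-3 * u3 + 4 * u2 + u),
        0.5 * (u3 - u2),
    ], axis=-1)
    dw = np.stack([
        0.5 * (-3 * u2 + 4 * u - 1),
        0.5 * (9 * u2 - 10 * u),
        0.5 * (-9 * u2 + 8 * u + 1),
        0.5 * (3 * u2 - 2 * u),
    ], axis=-1)
    return w, dw


def _linear_weights(u):
    w = np.stack([1 - u, u], axis=-1)
    dw = np.stack([-np.ones_like(u), np.ones_like(u)], axis=-1)
    return w, dw


def interpolate(dmap: DensityMap, points, order: str = "cubic"
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolated density and analytic gradient at Cartesian points.

    Returns ``(values, gradients, inside)``.  Points outside the
    interpolable margin get value 0 and gradient 0 with ``inside`` False.
    Accepts a single (3,) point or an (N, 3) array.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    if single:
        pts = pts[None]
    t = (pts - dmap.origin) / dmap.voxel
    n = np.array(dmap.shape)

    if order == "cubic":
        i0 = np.floor(t).astype(int)
        inside = np.all((i0 >= 1) & (i0 + 2 <= n - 1), axis=1)
        stencil, (wfun, lo) = 4, (_catmull_rom_weights, -1)
    elif order == "linear":
        i0 = np.floor(t).astype(int)
        inside = np.all((i0 >= 0) & (i0 + 1 <= n - 1), axis=1)
        stencil, (wfun, lo) = 2, (_linear_weights, 0)
    else:
        raise MapError(f"unknown interpolation order {order!r}")

    vals = np.zeros(len(pts))
    grads = np.zeros((len(pts), 3))
    if np.any(inside):
        ii = i0[inside]
        u = t[inside] - ii
        wx, dwx = wfun(u[:, 0])
        wy, dwy = wfun(u[:, 1])
        wz, dwz = wfun(u[:, 2])
        offs = np.arange(lo, lo + stencil)
        cube = dmap.values[
            (ii[:, 0, None, None, None] + offs[:, None, None]),
            (ii[:, 1, None, None, None] + offs[None, :, None]),
            (ii[:, 2, None, None, None] + offs[None, None, :])]
        vals[inside] = np.einsum("nijk,ni,nj,nk->n", cube, wx, wy, wz)
        grads[inside, 0] = np.einsum("nijk,ni,nj,nk->n", cube, dwx, wy, wz) / dmap.voxel[0]
        grads[inside, 1] = np.einsum("nijk,ni,nj,nk->n", cube, wx, dwy, wz) / dmap.voxel[1]
        grads[inside, 2] = np.einsum("nijk,ni,nj,nk->n", cube, wx, wy, dwz) / dmap.voxel[2]
    n_out = int((~inside).sum())
    if n_out:
        log.debug("%d point(s) outside the map feel no map force", n_out)
    if single:
        return vals[0], grads[0], inside[0]
    return vals, grads, inside


# ---------------------------------------------------------------------------
# the potential
# ---------------------------------------------------------------------------

@dataclass
class DensityMapPotential:
    """Couples a map to a simulation with E = -w * sum_i rho_hat(x_i).

    ``weight`` is in kJ/mol per sigma-normalized density unit.
    Normalization makes the weight transferable across maps: scaling the
    raw map values leaves the forces unchanged.
    """
    map: DensityMap
    weight: float
    interpolation: str = "cubic"
    _normalized: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.weight < 0:
            raise MapError("map coupling weight must be >= 0")
        self.refresh()

    def refresh(self) -> None:
        """Recompute the normalized grid after the map is mutated."""
        s = self.map.stats
        sigma = s["sigma"] if s["sigma"] > 0 else 1.0
        self._normalized = (self.map.values - s["mean"]) / sigma

    @property
    def normalized_map(self) -> DensityMap:
        return DensityMap(self._normalized, self.map.origin, self.map.voxel)


def mdff_energy(potential: DensityMapPotential, positions,
                enabled=None) -> tuple[float, np.ndarray]:
    """Energy and per-atom forces of the map potential.

    ``enabled`` is an optional boolean mask or index array selecting the
    atoms that feel the map (the caller passes heavy atoms only).
    """
    pos = np.asarray(positions, dtype=float)
    forces = np.zeros_like(pos)
    if enabled is None:
        sel = np.arange(len(pos))
    else:
        enabled = np.asarray(enabled)
        sel = np.nonzero(enabled)[0] if enabled.dtype == bool else enabled
    if len(sel) == 0:
        return 0.0, forces
    vals, grads, _ = interpolate(potential.normalized_map, pos[sel],
                                 order=potential.interpolation)
    energy = -potential.weight * float(vals.sum())
    forces[sel] = potential.weight * grads
    return energy, forces


# ---------------------------------------------------------------------------
# masking and synthetic maps
# ---------------------------------------------------------------------------

def mask_map(dmap: DensityMap, model: StructureModel, selection,
             radius: float = DEFAULT_MASK_RADIUS) -> DensityMap:
    """Zero all voxels farther than ``radius`` from every selected heavy atom.

    The input map is left untouched; masking is idempotent for a fixed
    selection and radius.
    """
    from scipy.spatial import cKDTree

    keys = set()
    for s in selection:
        res = s if not isinstance(s, tuple) else model.residue(s)
        keys.add(res.key)
    pts = []
    for r in model.residues():
        if r.key in keys:
            pts.extend(a.position for a in r.heavy_atoms())
    if not pts:
        raise MapError("empty selection for map masking")
    tree = cKDTree(np.array(pts))
    centres = dmap.voxel_centres()
    dist, _ = tree.query(centres)
    keep = (dist <= radius).reshape(dmap.shape)
    out = dmap.copy()
    out.values[~keep] = 0.0
    return out


def map_from_model(model: StructureModel, resolution_sigma: float,
                   voxel: float = 0.5, padding: float = 4.0) -> DensityMap:
    """Synthesize a Gaussian-blob density from a model.

    Each heavy atom contributes a unit-amplitude isotropic Gaussian of
    width ``resolution_sigma``; the grid pads the model's bounding box by
    ``padding`` on every side.  Used as synthetic ground truth for
    parameter-recovery tests.
    """
    if resolution_sigma <= 0 or voxel <= 0:
        raise MapError("resolution_sigma and voxel must be positive")
    coords = np.array([a.position for _, a in model.atoms()
                       if not a.is_hydrogen])
    if len(coords) == 0:
        raise MapError("model has no heavy atoms")
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 2)
    values = np.zeros(shape)
    axes = [lo[d] + np.arange(shape[d]) * voxel for d in range(3)]
    reach = 5.0 * resolution_sigma
    for c in coords:
        sl, local = [], []
        for d in range(3):
            j0 = max(0, int((c[d] - reach - lo[d]) / voxel))
            j1 = min(shape[d], int((c[d] + reach - lo[d]) / voxel) + 2)
            sl.append(slice(j0, j1))
            local.append(axes[d][j0:j1] - c[d])
        gx = np.exp(-0.5 * (local[0] / resolution_sigma) ** 2)
        gy = np.exp(-0.5 * (local[1] / resolution_sigma) ** 2)
        gz = np.exp(-0.5 * (local[2] / resolution_sigma) ** 2)
        values[sl[0], sl[1], sl[2]] += \
            gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    return DensityMap(values=values, origin=lo,
                      voxel=np.full(3, float(voxel)))
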