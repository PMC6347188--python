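"""Ligand-density grid and steric-hindrance scoring of receptor models.

The orthosteric peptide pocket is discretized on a regular Cartesian grid
(1 Angstrom spacing by default). Every heavy atom of every superposed
endogenous-peptide pose is binned into the cell containing it, all atoms
weighted equally; the per-cell counts form the ligand density. Cells with
nonzero density are the *core* region — the space the natural ligand actually
occupies — and the zero-density cells touching the core form a *shell*
around it (useful for small-molecule sites; unused by default scoring).

A receptor model's steric-hindrance score is the number of core cells that
contain at least one receptor heavy atom: homology models whose extracellular
loops collapse into the pocket light up many occupied cells and get high
scores, and can be filtered out before energy evaluation and docking.
Cell coverage counts cells, not atoms — a cell hit by three receptor atoms
contributes one — and "covered" means an atom *center* falls inside the cell,
mirroring the ligand binning rule (no atomic radii).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import InputError
from .structio import StructureModel

__all__ = [
    "DensityGrid",
    "GridRegion",
    "StericScore",
    "build_density_grid",
    "grid_regions",
    "steric_score",
    "derive_box",
]

#: scipy connectivity orders for the 6 / 18 / 26 cell neighbourhoods.
_CONNECTIVITY_ORDER = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True, eq=False)
class DensityGrid:
    """Regular 3-D occupancy grid over a binding site.

    ``counts[i, j, k]`` is the number of ligand heavy atoms whose coordinates
    fall in cell (i, j, k). Cells are half-open boxes
    ``[origin + i*s, origin + (i+1)*s)`` per axis, so every point maps to
    exactly one cell; points landing exactly on the upper grid boundary are
    binned into the last cell so no atom inside the bounding box is lost.
    """

    origin: tuple[float, float, float]
    spacing: float
    counts: np.ndarray  # (nx, ny, nz) int array

    def __post_init__(self):
        if self.spacing <= 0:
            raise InputError(f"grid spacing must be > 0, got {self.spacing}")
        if self.counts.ndim != 3 or min(self.counts.shape) < 1:
            raise InputError("grid counts must be a non-empty 3-D array")
        if (self.counts < 0).any():
            raise InputError("grid counts must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def n_ligand_atoms_binned(self) -> int:
        return int(self.counts.sum())

    def cell_indices(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (n, 3) points to cell index triples.

        Returns ``(indices, inside)`` where ``inside`` flags points within
        the grid bounds; indices of outside points are meaningless.
        Points exactly on the upper boundary belong to the last cell.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = (pts - np.asarray(self.origin)) / self.spacing
        idx = np.floor(rel).astype(int)
        dims = np.asarray(self.dims)
        on_upper_edge = (idx == dims) & np.isclose(rel, dims)
        idx = np.where(on_upper_edge, dims - 1, idx)
        inside = ((idx >= 0) & (idx < dims)).all(axis=1)
        return idx, inside

    def cell_center(self, index: Sequence[int]) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(index) + 0.5) * self.spacing


@dataclass(frozen=True)
class GridRegion:
    """A set of grid cells: the ligand-occupied core or its surrounding shell."""

    cells: frozenset[tuple[int, int, int]]
    kind: str  # "core" | "shell"
    dims: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class StericScore:
    """Number of ligand-occupied cells intruded upon by a receptor model."""

    model_id: str
    score: int

    def __post_init__(self):
        if self.score < 0:
            raise InputError("steric score cannot be negative")


def build_density_grid(
    ligand_poses: Iterable[StructureModel],
    spacing: float = 1.0,
    padding: float = 2.0,
) -> DensityGrid:
    """Bin the heavy atoms of superposed ligand poses onto a Cartesian grid.

    The grid covers the axis-aligned bounding box of all ligand heavy atoms
    expanded by ``padding`` on every side (the default 2 A leaves room for the
    shell region inside the bounds), discretized at ``spacing``.
    """
    poses = list(ligand_poses)
    if not poses:
        raise InputError("need at least one ligand pose to build a grid")
    if spacing <= 0:
        raise InputError(f"grid spacing must be > 0, got {spacing}")
    coords = [p.coordinates(heavy_only=True) for p in poses]
    coords = [c for c in coords if len(c)]
    if not coords:
        raise InputError("ligand poses contain no heavy atoms")
    pts = np.concatenate(coords)
    # Snap the origin to the spacing lattice: cell boundaries then sit at
    # integer multiples of the spacing, so binning is stable under shifts by
    # whole cells and an atom never sits on a cell edge merely because it
    # defined the bounding box.
    lo = np.floor((pts.min(axis=0) - padding) / spacing) * spacing
    hi = pts.max(axis=0) + padding
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    grid = DensityGrid(
        origin=tuple(lo), spacing=float(spacing),
        counts=np.zeros(tuple(dims), dtype=int),
    )
    idx, inside = grid.cell_indices(pts)
    assert inside.all(), "bounding-box construction lost an atom"
    np.add.at(grid.counts, tuple(idx.T), 1)
    grid.counts.flags.writeable = False
    return grid


def grid_regions(
    grid: DensityGrid, connectivity: int = 26
) -> tuple[GridRegion, GridRegion]:
    """Split a density grid into its core and shell regions.

    core: cells with nonzero ligand density. shell: zero-density cells with at
    least one nonzero cell among their neighbours. The neighbourhood is
    26-connected by default (6 and 18 also supported); the source procedure
    says only "neighboring grid points", so the choice is explicit here.
    """
    if connectivity not in _CONNECTIVITY_ORDER:
        raise InputError(
            f"connectivity must be one of {sorted(_CONNECTIVITY_ORDER)}, "
            f"got {connectivity}"
        )
    core_mask = grid.counts > 0
    structure = ndimage.generate_binary_structure(
        3, _CONNECTIVITY_ORDER[connectivity]
    )
    shell_mask = ndimage.binary_dilation(core_mask, structure) & ~core_mask
    to_cells = lambda mask: frozenset(
        map(tuple, np.argwhere(mask).tolist())
    )
    dims = grid.dims
    return (
        GridRegion(cells=to_cells(core_mask), kind="core", dims=dims),
        GridRegion(cells=to_cells(shell_mask), kind="shell", dims=dims),
    )


def steric_score(
    grid: DensityGrid, receptor: StructureModel, region: GridRegion
) -> StericScore:
    """Count region cells containing at least one receptor heavy-atom center.

    Receptor atoms outside the grid bounds contribute nothing. Scoring against
    the core region gives the steric-hindrance score used for ensemble
    filtering; scoring against the shell is exposed for small-molecule sites.
    """
    if not receptor.atoms:
        raise InputError(f"receptor {receptor.id!r} is empty")
    if region.dims != grid.dims:
        raise InputError(
            f"region was derived from a {region.dims} grid, scoring against "
            f"a {grid.dims} grid"
        )
    pts = receptor.coordinates(heavy_only=True)
    if len(pts) == 0:
        return StericScore(model_id=receptor.id, score=0)
    idx, inside = grid.cell_indices(pts)
    occupied = {tuple(t) for t in idx[inside].tolist()}
    return StericScore(
        model_id=receptor.id, score=len(occupied & region.cells)
    )


def derive_box(
    grid: DensityGrid,
    margin: float,
    receptor_id: str = "",
    site: str = "orthosteric",
):
    """Docking-box specification enclosing the ligand-occupied core.

    Center = centroid of core-cell centers; size = core bounding-box extents
    plus ``2 * margin`` per axis. Intended to seed per-receptor/per-site box
    configs for an external docking engine.
    """
    from .dockadapter import BoxSpec  # adapter owns the box contract

    core_idx = np.argwhere(grid.counts > 0)
    if len(core_idx) == 0:
        raise InputError("cannot derive a docking box from an all-zero grid")
    centers = np.asarray(grid.origin) + (core_idx + 0.5) * grid.spacing
    extent = (core_idx.max(axis=0) - core_idx.min(axis=0) + 1) * grid.spacing
    return BoxSpec(
        receptor_id=receptor_id,
        site=site,
        center=tuple(centers.mean(axis=0)),
        size=tuple(extent + 2.0 * margin),
    )
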