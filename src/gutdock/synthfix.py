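"""Synthetic data generators and packaged fixtures.

Everything in the pipeline is testable without downloads: toy
peptide-pose/receptor complexes with a known planted steric score, score
libraries with planted enrichment (defaulting to the study design of 10
actives and 500 decoys), drug-by-receptor score matrices with a planted
rank-score correlation, the two published clinical rank assignments for the
reference beta-blockers, the printed self-docking receptor score sets, and a
canned engine-output file plus a stub executable for exercising the docking
adapter. All randomness flows from one explicit seed per generator call.
"""

from __future__ import annotations

import os
import stat
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import InputError
from .offtarget import RECEPTORS, SITES, ClinicalRankTable, ScoreMatrix
from .stericgrid import DensityGrid, build_density_grid
from .structio import Atom, StructureModel
from .vsmetrics import ScoredLibrary

__all__ = [
    "ToyComplexSpec",
    "ToyComplex",
    "PlantedEnrichmentSpec",
    "PlantedCorrelationSpec",
    "gen_toy_complex",
    "gen_scored_library",
    "gen_score_matrix",
    "fig3_ranks",
    "table3_ranks",
    "rank_table",
    "COMPOUND15_IUPAC",
    "SELFDOCK_SCORES",
    "CANNED_VINA_OUTPUT",
    "write_stub_engine",
]

# --------------------------------------------------------------------------
# Packaged fixtures
# --------------------------------------------------------------------------

#: The blind-test beta-blocker: a negative allosteric modulator of the
#: beta-2 adrenergic receptor, carrying no clinical T2DM data yet (rank 0).
COMPOUND15_IUPAC = (
    "4-((2S)-3-(((S)-3-(3-bromophenyl)-1-(methylamino)-1-oxopropan-2-yl)"
    "amino)-2-(2-cyclohexyl-2-phenylacetamido)-3-oxopropyl)benzamide"
)

# The two published T2DM-risk rank assignments for the reference
# beta-blockers disagree on the nebivolol/carvedilol order; both ship.
_FIG3_RANKS = {
    "compound 15": 0,  # no clinical data
    "carvedilol": 1,
    "nebivolol": 2,
    "labetalol": 3,
    "atenolol": 4,
    "metoprolol": 5,
}
_TABLE3_RANKS = {
    "nebivolol": 1,
    "carvedilol": 1,  # tied in the medical-information column
    "labetalol": 2,
    "atenolol": 3,
    "metoprolol": 4,
}

#: Printed receptor score sets of the self-docking validation: one per
#: crystal ligand, lower = stronger; the true receptor should win.
SELFDOCK_SCORES = {
    "GLP1R_crystal_ligand": {
        "GLP1R": -8.2, "GCGR": -7.0, "GIPR": -6.5, "VIPR1": -8.0,
        "PAC1R": -6.8,
    },
    "GCGR_crystal_ligand": {
        "GCGR": -8.9, "GIPR": -8.7, "GLP1R": -8.6, "VIPR1": -8.0,
        "PAC1R": -7.6,
    },
}


def fig3_ranks() -> ClinicalRankTable:
    """Default rank assignment (carvedilol = 1, nebivolol = 2, ... ,
    compound 15 = 0 for 'no clinical data')."""
    return ClinicalRankTable(entries=dict(_FIG3_RANKS), name="fig3")


def table3_ranks() -> ClinicalRankTable:
    """Alternative assignment from the risk-ranking table's
    medical-information column (nebivolol and carvedilol tied at 1)."""
    return ClinicalRankTable(entries=dict(_TABLE3_RANKS), name="table3")


def rank_table(which: str = "fig3") -> ClinicalRankTable:
    if which == "fig3":
        return fig3_ranks()
    if which == "table3":
        return table3_ranks()
    raise InputError(f"unknown rank assignment {which!r} (fig3 or table3)")


def _pose_block(rank: int, score: float, shift: float) -> str:
    lines = [
        f"MODEL {rank}",
        f"REMARK VINA RESULT:    {score:8.3f}      0.000      0.000",
    ]
    coords = [(0.0, 0.0, 0.0), (1.4, 0.0, 0.0), (2.1, 1.2, 0.0), (3.5, 1.2, 0.1)]
    names = ["C1", "C2", "O1", "N1"]
    elements = ["C", "C", "OA", "NA"]
    for i, ((x, y, z), name, el) in enumerate(zip(coords, names, elements), 1):
        lines.append(
            f"ATOM  {i:>5} {name:<4} LIG A   1    "
            f"{x + shift:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}    "
            f"{0.0:+6.3f} {el:<2}"
        )
    lines.append("ENDMDL")
    return "\n".join(lines)


#: Canned engine output: three scored ligand poses in the PDBQT dialect.
CANNED_VINA_OUTPUT = (
    "\n".join(
        _pose_block(rank, score, shift)
        for rank, (score, shift) in enumerate(
            [(-8.2, 0.0), (-7.9, 0.5), (-7.1, 1.0)], 1
        )
    )
    + "\n"
)


def write_stub_engine(
    path,
    output_text: str = CANNED_VINA_OUTPUT,
    exit_code: int = 0,
) -> Path:
    """Write an executable stand-in for the docking engine (synthetic).

    The stub accepts the engine-convention flag set, ignores everything but
    ``--out``, writes ``output_text`` there and exits with ``exit_code`` —
    enough to exercise the adapter contract end to end without a real engine.
    """
    path = Path(path)
    payload = output_text.replace("\\", "\\\\").replace('"""', r'\"\"\"')
    path.write_text(
        "#!/usr/bin/env python3\n"
        "import sys\n"
        "args = sys.argv[1:]\n"
        "out = args[args.index('--out') + 1]\n"
        f'open(out, "w").write("""{payload}""")\n'
        f"sys.exit({exit_code})\n"
    )
    path.chmod(path.stat().st_mode | stat.S_IXUSR | stat.S_IXGRP | stat.S_IXOTH)
    return path


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a toy pocket: superposed peptide poses plus a receptor
    whose intrusion into the ligand-occupied grid region is controlled."""

    n_poses: int = 5
    n_atoms_per_pose: int = 30
    pocket_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pocket_radius: float = 6.0
    receptor_intrusion: int = 0
    n_receptor_shell_atoms: int = 60
    seed: int = 0

    def __post_init__(self):
        if min(self.n_poses, self.n_atoms_per_pose) < 1:
            raise InputError("pose and atom counts must be positive")
        if self.pocket_radius <= 0:
            raise InputError("pocket radius must be positive")
        if self.receptor_intrusion < 0 or self.n_receptor_shell_atoms < 0:
            raise InputError("receptor atom counts cannot be negative")


@dataclass(frozen=True, eq=False)
class ToyComplex:
    """Generated complex plus the planted ground truth for oracle tests."""

    poses: tuple[StructureModel, ...]
    receptor: StructureModel
    grid: DensityGrid
    true_steric_score: int


@dataclass(frozen=True)
class PlantedEnrichmentSpec:
    """Score library with a planted active/decoy separation.

    Defaults mirror the screen design used to validate receptor models:
    10 known actives against 500 decoys. ``separation`` is the active/decoy
    score-mean gap in units of the shared noise sigma, on a lower-is-better
    scale.
    """

    n_actives: int = 10
    n_decoys: int = 500
    separation: float = 2.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_actives, self.n_decoys) < 1:
            raise InputError("need at least one active and one decoy")
        if self.sigma <= 0:
            raise InputError("noise sigma must be positive")


@dataclass(frozen=True)
class PlantedCorrelationSpec:
    """Drug-by-receptor score matrix with a planted rank-score correlation.

    Five drugs with ranks 1..n_drugs, the five-receptor/two-site key set,
    and per-key scores whose sample Pearson correlation with the rank equals
    ``rho`` exactly (see :func:`gen_score_matrix`).
    """

    n_drugs: int = 5
    rho: float = 0.9
    noise_sigma: float = 0.6
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if abs(self.rho) > 1:
            raise InputError(f"|rho| must be <= 1, got {self.rho}")
        if self.n_drugs < 3:
            raise InputError("need at least 3 drugs for a correlation")
        if self.n_replicates < 1:
            raise InputError("need at least one replicate")
        if self.noise_sigma < 0:
            raise InputError("noise sigma cannot be negative")


def _uniform_ball(rng, n: int, center, radius: float) -> np.ndarray:
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1 / 3)
    return np.asarray(center) + direction * r[:, None]


def _cloud_model(
    model_id, coords, element="C", residue="LIG", chain="L"
) -> StructureModel:
    atoms = tuple(
        Atom(
            serial=i,
            name=f"{element}{i}",
            element=element,
            residue_name=residue,
            residue_number=1,
            chain=chain,
            coordinates=tuple(xyz),
        )
        for i, xyz in enumerate(np.asarray(coords, dtype=float), 1)
    )
    return StructureModel(id=model_id, atoms=atoms, source_format="PDB")


def gen_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Generate superposed ligand poses and a receptor with known intrusion.

    Poses are uniform atom clouds inside the pocket sphere. The receptor
    places exactly ``receptor_intrusion`` atoms at the centers of distinct
    ligand-occupied (core) grid cells and the rest on a sphere outside the
    grid bounds, so the true steric score equals ``receptor_intrusion`` by
    construction and is returned alongside for oracle testing.
    """
    rng = np.random.default_rng(spec.seed)
    poses = tuple(
        _cloud_model(
            f"pose_{i + 1}",
            _uniform_ball(
                rng, spec.n_atoms_per_pose, spec.pocket_center,
                spec.pocket_radius,
            ),
        )
        for i in range(spec.n_poses)
    )
    grid = build_density_grid(poses, spacing=1.0, padding=2.0)
    core_cells = sorted(map(tuple, np.argwhere(grid.counts > 0).tolist()))
    if spec.receptor_intrusion > len(core_cells):
        raise InputError(
            f"cannot place {spec.receptor_intrusion} intruding atoms: the "
            f"grid has only {len(core_cells)} ligand-occupied cells"
        )
    chosen = rng.choice(
        len(core_cells), size=spec.receptor_intrusion, replace=False
    )
    inside = [grid.cell_center(core_cells[i]) for i in sorted(chosen)]
    # shell atoms strictly outside the grid bounding box: zero contribution
    span = np.asarray(grid.dims) * grid.spacing
    shell_radius = float(np.linalg.norm(span)) + 2.0 * grid.spacing
    grid_center = np.asarray(grid.origin) + span / 2
    outside = _uniform_ball(
        rng, spec.n_receptor_shell_atoms, (0.0, 0.0, 0.0), 1.0
    )
    outside = grid_center + shell_radius * (
        outside / np.linalg.norm(outside, axis=1, keepdims=True)
    )
    coords = np.concatenate([np.asarray(inside).reshape(-1, 3), outside])
    receptor = _cloud_model(
        "receptor", coords, element="C", residue="REC", chain="R"
    )
    return ToyComplex(
        poses=poses,
        receptor=receptor,
        grid=grid,
        true_steric_score=int(spec.receptor_intrusion),
    )


def gen_scored_library(spec: PlantedEnrichmentSpec) -> ScoredLibrary:
    """Score library with Gaussian actives shifted below Gaussian decoys.

    Active scores ~ N(-separation * sigma, sigma), decoys ~ N(0, sigma),
    lower-is-better; the planted AUC is Phi(separation / sqrt(2)).
    """
    rng = np.random.default_rng(spec.seed)
    active_scores = rng.normal(
        -spec.separation * spec.sigma, spec.sigma, spec.n_actives
    )
    decoy_scores = rng.normal(0.0, spec.sigma, spec.n_decoys)
    width_a = len(str(spec.n_actives))
    width_d = len(str(spec.n_decoys))
    return ScoredLibrary(
        ids=tuple(
            [f"active_{i + 1:0{width_a}d}" for i in range(spec.n_actives)]
            + [f"decoy_{i + 1:0{width_d}d}" for i in range(spec.n_decoys)]
        ),
        scores=np.concatenate([active_scores, decoy_scores]),
        is_active=np.concatenate(
            [np.ones(spec.n_actives, bool), np.zeros(spec.n_decoys, bool)]
        ),
        score_direction="lower_better",
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    c = v - v.mean()
    return c / np.linalg.norm(c)


def gen_score_matrix(
    spec: PlantedCorrelationSpec,
) -> tuple[ScoreMatrix, ClinicalRankTable]:
    """Score matrix whose per-key sample rank-score correlation is ``rho``.

    Per (receptor, site) and replicate, the score vector is an orthogonalized
    mixture ``rho * z_rank + sqrt(1 - rho^2) * z_noise`` of the standardized
    rank vector and standardized noise orthogonal to it, rescaled by
    ``noise_sigma`` around a typical docking baseline. This plants the
    *sample* Pearson coefficient exactly (not just its population value), so
    recovery studies are free of the small-n estimator bias.
    """
    rng = np.random.default_rng(spec.seed)
    drugs = [f"drug_{i:02d}" for i in range(1, spec.n_drugs + 1)]
    ranks = ClinicalRankTable(
        entries={d: i for i, d in enumerate(drugs, 1)}, name="synthetic"
    )
    z_rank = _standardize(np.arange(1, spec.n_drugs + 1, dtype=float))
    rows = []
    for receptor in RECEPTORS:
        for site in SITES:
            for rep in range(1, spec.n_replicates + 1):
                z_noise = None
                while z_noise is None:
                    e = rng.normal(size=spec.n_drugs)
                    e = e - e.mean() - (e @ z_rank) * z_rank
                    norm = np.linalg.norm(e)
                    if norm > 1e-8:
                        z_noise = e / norm
                mix = (
                    spec.rho * z_rank
                    + np.sqrt(1 - spec.rho**2) * z_noise
                )
                scores = -8.0 + spec.noise_sigma * mix * np.sqrt(spec.n_drugs)
                rows.extend(
                    (drug, receptor, site, rep, float(s))
                    for drug, s in zip(drugs, scores)
                )
    import pandas as pd

    matrix = ScoreMatrix(
        table=pd.DataFrame(
            rows, columns=["drug", "receptor", "site", "replicate", "score"]
        ),
        engine="synthetic",
    )
    return matrix, ranks
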