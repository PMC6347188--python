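"""Molecular structure I/O and pose geometry.

Reads and writes receptor models and ligand poses in PDB (via gemmi) and in
the AutoDock PDBQT dialect (fixed-column reader/writer, since PDBQT stores an
AutoDock atom type and a partial charge where PDB keeps the element and charge
columns). Provides heavy-atom selection, superposition-free ligand-pose RMSD,
and attachment of generic transmembrane residue numbers (Wootten scheme for
class B GPCRs, e.g. "6.41").

All coordinates are Cartesian, in Angstrom, and are assumed to live in a
common frame across an ensemble: no fitting is performed anywhere in the
package (model ensembles are built on a shared template frame).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import ConfigError, CorrespondenceError, InputError, ParseError

__all__ = [
    "Atom",
    "StructureModel",
    "GenericNumberMap",
    "read_structure",
    "read_models",
    "write_structure",
    "heavy_atoms",
    "pose_rmsd",
    "assign_generic_numbers",
]

#: Elements counted as hydrogen for heavy-atom selection (D = deuterium).
_HYDROGEN = {"H", "D"}

# AutoDock atom types that do not equal their element symbol.
_AUTODOCK_TYPE_TO_ELEMENT = {
    "A": "C",    # aromatic carbon
    "HD": "H", "HS": "H",
    "NA": "N", "NS": "N",
    "OA": "O", "OS": "O",
    "SA": "S",
    "CL": "Cl", "BR": "Br", "FE": "Fe", "ZN": "Zn", "MG": "Mg",
    "MN": "Mn", "CA": "Ca",
}

_GENERIC_LABEL_RE = re.compile(r"^\d+\.\d+$")


@dataclass(frozen=True)
class Atom:
    """One atom record: identity, residue context and position (Angstrom)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    coordinates: tuple[float, float, float]
    generic_number: str | None = None

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.coordinates):
            raise InputError(f"atom {self.serial} has non-finite coordinates")

    @property
    def is_heavy(self) -> bool:
        return self.element.capitalize() not in _HYDROGEN

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coordinates, dtype=float)


@dataclass(frozen=True)
class StructureModel:
    """An ordered collection of atoms (a receptor model or a ligand pose)."""

    id: str
    atoms: tuple[Atom, ...]
    source_format: str = "PDB"

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise InputError(f"model {self.id!r}: duplicate atom serials")

    def __len__(self) -> int:
        return len(self.atoms)

    def heavy_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.is_heavy)

    def coordinates(self, heavy_only: bool = False) -> np.ndarray:
        """(n, 3) coordinate array, optionally restricted to heavy atoms."""
        sel = self.heavy_atoms() if heavy_only else self.atoms
        if not sel:
            return np.empty((0, 3))
        return np.stack([a.xyz for a in sel])

    def translated(self, vector) -> "StructureModel":
        """A copy rigidly shifted by ``vector`` (Angstrom)."""
        v = np.asarray(vector, dtype=float)
        moved = tuple(
            replace(a, coordinates=tuple(a.xyz + v)) for a in self.atoms
        )
        return replace(self, atoms=moved)


@dataclass(frozen=True)
class GenericNumberMap:
    """(chain, residue_number) -> generic residue label, e.g. ``"6.41"``.

    Labels must look like ``digit(s).digit(s)`` and be unique within a chain;
    a duplicated label would make the scheme ambiguous and is rejected.
    """

    entries: Mapping[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self):
        per_chain: dict[str, set[str]] = {}
        for (chain, resnum), label in self.entries.items():
            if not _GENERIC_LABEL_RE.match(label):
                raise ConfigError(
                    f"generic label {label!r} for {chain}/{resnum} does not "
                    "match the digit(s).digit(s) pattern"
                )
            seen = per_chain.setdefault(chain, set())
            if label in seen:
                raise ConfigError(
                    f"generic label {label!r} assigned to two residues of "
                    f"chain {chain!r}"
                )
            seen.add(label)

    @classmethod
    def from_file(cls, path) -> "GenericNumberMap":
        """Read a whitespace-separated ``chain residue_number label`` file.

        Blank lines and ``#`` comments are ignored.
        """
        entries: dict[tuple[str, int], str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 'chain resnum label', "
                    f"got {raw!r}"
                )
            chain, resnum, label = parts
            try:
                entries[(chain, int(resnum))] = label
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: residue number {resnum!r} is not an "
                    "integer"
                ) from exc
        return cls(entries=dict(entries))


def _element_from_name(name: str) -> str:
    """Fallback element guess: first alphabetic character of the atom name.

    PDB files in the wild often omit the element column; the leading letter of
    the atom name (after any digits, e.g. ``1HB``) is the usual convention.
    """
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _dedup_altlocs(records):
    """Keep the highest-occupancy alternate location per (chain, res, name)."""
    best: dict[tuple, tuple[float, int, object]] = {}
    order = []
    for i, rec in enumerate(records):
        key = (rec["chain"], rec["residue_number"], rec["name"])
        if rec["altloc"] in ("", " "):
            key = key + (i,)  # no altloc: never collapse distinct records
        if key not in best:
            best[key] = (rec["occ"], -i, rec)
            order.append(key)
        elif rec["occ"] > best[key][0]:
            best[key] = (rec["occ"], -i, rec)
    return [best[k][2] for k in order]


def _records_to_model(records, model_id: str, fmt: str) -> StructureModel:
    records = _dedup_altlocs(records)
    atoms = tuple(
        Atom(
            serial=r["serial"],
            name=r["name"],
            element=r["element"],
            residue_name=r["residue_name"],
            residue_number=r["residue_number"],
            chain=r["chain"],
            coordinates=r["coordinates"],
        )
        for r in records
    )
    return StructureModel(id=model_id, atoms=atoms, source_format=fmt)


def _read_pdb_models(path) -> list[StructureModel]:
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path} as PDB: {exc}") from exc
    models = []
    for mi, gm in enumerate(st, 1):
        records = []
        for chain in gm:
            for res in chain:
                for at in res:
                    el = at.element.name
                    if el in ("", "X"):
                        el = _element_from_name(at.name)
                    records.append(
                        {
                            "serial": at.serial,
                            "name": at.name,
                            "element": el,
                            "residue_name": res.name,
                            "residue_number": res.seqid.num,
                            "chain": chain.name,
                            "coordinates": (at.pos.x, at.pos.y, at.pos.z),
                            "altloc": at.altloc or "",
                            "occ": at.occ,
                        }
                    )
        if records:
            mid = Path(path).stem if len(st) == 1 else f"{Path(path).stem}_{mi}"
            models.append(_records_to_model(records, mid, "PDB"))
    return models


def _parse_pdbqt_atom_line(line: str, lineno: int) -> dict:
    try:
        adtype = line[77:79].strip() or line[76:79].strip()
        element = _AUTODOCK_TYPE_TO_ELEMENT.get(
            adtype.upper(), adtype.capitalize() or None
        )
        if not element:
            element = _element_from_name(line[12:16].strip())
        return {
            "serial": int(line[6:11]),
            "name": line[12:16].strip(),
            "element": element,
            "residue_name": line[17:21].strip(),
            "residue_number": int(line[22:26]),
            "chain": line[21].strip() or "A",
            "coordinates": (
                float(line[30:38]),
                float(line[38:46]),
                float(line[46:54]),
            ),
            "altloc": line[16].strip(),
            "occ": float(line[54:60]) if line[54:60].strip() else 1.0,
        }
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed PDBQT atom record") from exc


def _read_pdbqt_models(path) -> list[StructureModel]:
    # BRANCH/TORSDOF/ROOT torsion-tree records and REMARK lines (including the
    # engine's score REMARKs) are ignored: only atom records matter here.
    models: list[StructureModel] = []
    records: list[dict] = []
    n_models = 0
    stem = Path(path).stem
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        tag = line[:6].strip()
        if tag in ("ATOM", "HETATM"):
            records.append(_parse_pdbqt_atom_line(line, lineno))
        elif tag == "ENDMDL" and records:
            n_models += 1
            models.append(
                _records_to_model(records, f"{stem}_{n_models}", "PDBQT")
            )
            records = []
    if records:
        mid = stem if n_models == 0 else f"{stem}_{n_models + 1}"
        models.append(_records_to_model(records, mid, "PDBQT"))
    return models


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.upper()
        if f not in ("PDB", "PDBQT"):
            raise InputError(f"unknown structure format {fmt!r}")
        return f
    return "PDBQT" if str(path).lower().endswith(".pdbqt") else "PDB"


def read_models(path, format: str | None = None) -> list[StructureModel]:
    """Read every MODEL block of a file as a separate :class:`StructureModel`.

    A file without MODEL records yields a single-element list.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such structure file: {path}")
    fmt = _infer_format(path, format)
    models = (
        _read_pdbqt_models(path) if fmt == "PDBQT" else _read_pdb_models(path)
    )
    if not models:
        raise InputError(f"{path}: no ATOM/HETATM records found")
    return models


def read_structure(path, format: str | None = None) -> StructureModel:
    """Read a structure file; for multi-MODEL files the first model is kept."""
    return read_models(path, format=format)[0]


def write_structure(model: StructureModel, path, format: str | None = None):
    """Write a model as PDB (via gemmi) or PDBQT (fixed-column records)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "PDB":
        st = gemmi.Structure()
        st.name = model.id
        gm = gemmi.Model("1")
        # gemmi's add_residue/add_chain copy their argument, so residues and
        # chains must be fully populated before being added.
        grouped: dict[str, dict[tuple[int, str], list]] = {}
        for a in model.atoms:
            grouped.setdefault(a.chain, {}).setdefault(
                (a.residue_number, a.residue_name), []
            ).append(a)
        for chain_name, residues in grouped.items():
            chain = gemmi.Chain(chain_name)
            for (resnum, resname), atoms in residues.items():
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                for a in atoms:
                    at = gemmi.Atom()
                    at.name = a.name
                    at.serial = a.serial
                    at.element = gemmi.Element(a.element)
                    at.pos = gemmi.Position(*a.coordinates)
                    at.occ = 1.0
                    at.b_iso = 0.0
                    res.add_atom(at)
                chain.add_residue(res)
            gm.add_chain(chain)
        st.add_model(gm)
        st.setup_entities()
        st.write_pdb(str(path))
    else:
        lines = []
        for a in model.atoms:
            lines.append(
                f"ATOM  {a.serial:>5} {a.name:<4} {a.residue_name:<4}"
                f"{a.chain[:1]}{a.residue_number:>4}    "
                f"{a.coordinates[0]:8.3f}{a.coordinates[1]:8.3f}"
                f"{a.coordinates[2]:8.3f}{1.0:6.2f}{0.0:6.2f}    "
                f"{0.0:+6.3f} {a.element:<2}"
            )
        lines.append("TER")
        path.write_text("\n".join(lines) + "\n")


def heavy_atoms(structure: StructureModel) -> tuple[Atom, ...]:
    """The non-hydrogen atoms of a structure, order preserved."""
    if not structure.atoms:
        raise InputError(f"model {structure.id!r} is empty")
    return structure.heavy_atoms()


def pose_rmsd(pose_a: StructureModel, pose_b: StructureModel) -> float:
    """Heavy-atom RMSD between two poses sharing the receptor frame.

    Correspondence is positional (i-th heavy atom against i-th heavy atom)
    and no superposition is applied: the quantity measures how far a docked
    pose lies from a reference orientation in the *same* frame, as in
    self-docking validation.
    """
    xa = pose_a.coordinates(heavy_only=True)
    xb = pose_b.coordinates(heavy_only=True)
    if xa.shape != xb.shape:
        raise CorrespondenceError(
            f"heavy-atom counts differ: {xa.shape[0]} vs {xb.shape[0]}"
        )
    if xa.shape[0] == 0:
        raise InputError("poses contain no heavy atoms")
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def assign_generic_numbers(
    structure: StructureModel, number_map: GenericNumberMap
) -> StructureModel:
    """Attach generic residue labels (e.g. Wootten numbers) to atoms.

    Residues absent from the map stay unlabeled; everything else about the
    structure is unchanged.
    """
    if not number_map.entries:
        return structure
    atoms = tuple(
        replace(a, generic_number=number_map.entries.get(
            (a.chain, a.residue_number)))
        if (a.chain, a.residue_number) in number_map.entries
        else a
        for a in structure.atoms
    )
    return replace(structure, atoms=atoms)
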