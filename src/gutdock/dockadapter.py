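"""Adapter for an external AutoDock-VINA-compatible docking engine.

No docking engine is implemented or modified here: the adapter owns the
invocation contract (receptor/ligand PDBQT files plus a per-receptor,
per-site search box), parses the engine's scored multi-MODEL PDBQT output,
and selects the best receptor for a ligand from a score map. Every other
module consumes score tables, so the whole package runs against a stub
executable in tests.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Optional, Sequence

from .errors import EngineError, InputError, ParseError
from .structio import StructureModel, read_models

__all__ = [
    "BoxSpec",
    "DockingResult",
    "BestReceptor",
    "run_docking",
    "parse_scores",
    "best_receptor",
]

_RESULT_RE = re.compile(r"^REMARK VINA RESULT:\s+(\S+)\s+(\S+)\s+(\S+)\s*$")


@dataclass(frozen=True)
class BoxSpec:
    """Search box for one receptor and binding site (center/size in Angstrom)."""

    receptor_id: str
    site: str
    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self):
        if self.site not in ("orthosteric", "allosteric"):
            raise InputError(f"unknown binding site {self.site!r}")
        if any(s <= 0 for s in self.size):
            raise InputError(f"box size components must be > 0, got {self.size}")

    def cli_args(self) -> list[str]:
        """The engine-convention center/size flags."""
        cx, cy, cz = self.center
        sx, sy, sz = self.size
        return [
            "--center_x", str(cx), "--center_y", str(cy), "--center_z", str(cz),
            "--size_x", str(sx), "--size_y", str(sy), "--size_z", str(sz),
        ]


@dataclass(frozen=True)
class DockingResult:
    """Scored ligand poses, best first (lower score = stronger binding)."""

    poses: tuple[tuple[StructureModel, float, int], ...]
    log: str = ""

    def __post_init__(self):
        scores = [s for _, s, _ in self.poses]
        if scores != sorted(scores):
            raise InputError("poses must be sorted by non-decreasing score")
        if [r for _, _, r in self.poses] != list(range(1, len(scores) + 1)):
            raise InputError("pose ranks must be contiguous from 1")

    @property
    def scores(self) -> list[float]:
        return [s for _, s, _ in self.poses]

    @property
    def best_score(self) -> float:
        return self.poses[0][1]

    def serialize(self) -> str:
        """Multi-MODEL PDBQT text with one score REMARK per pose."""
        blocks = []
        for model, score, rank in self.poses:
            lines = [f"MODEL {rank}",
                     f"REMARK VINA RESULT:    {score:8.3f}      0.000      0.000"]
            for a in model.atoms:
                lines.append(
                    f"ATOM  {a.serial:>5} {a.name:<4} {a.residue_name:<4}"
                    f"{a.chain[:1]}{a.residue_number:>4}    "
                    f"{a.coordinates[0]:8.3f}{a.coordinates[1]:8.3f}"
                    f"{a.coordinates[2]:8.3f}{1.0:6.2f}{0.0:6.2f}    "
                    f"{0.0:+6.3f} {a.element:<2}"
                )
            lines.append("ENDMDL")
            blocks.append("\n".join(lines))
        return "\n".join(blocks) + "\n"


class BestReceptor(NamedTuple):
    """Outcome of best-receptor selection over a ligand's score map."""

    receptor_id: str
    score: float
    margin: float  # gap to the runner-up (0.0 with a single receptor)
    ambiguous: bool  # True when the minimum is tied


def parse_scores(output_text: str) -> list[float]:
    """Extract engine scores from ``REMARK VINA RESULT`` lines, in file order.

    A line that starts like a result line but fails to parse raises a
    :class:`ParseError` naming the line number.
    """
    scores = []
    for lineno, line in enumerate(output_text.splitlines(), 1):
        if not line.startswith("REMARK VINA RESULT:"):
            continue
        m = _RESULT_RE.match(line)
        if not m:
            raise ParseError(f"line {lineno}: malformed engine result line")
        try:
            scores.append(float(m.group(1)))
        except ValueError as exc:
            raise ParseError(
                f"line {lineno}: engine score {m.group(1)!r} is not a number"
            ) from exc
    if not scores:
        raise ParseError("no 'REMARK VINA RESULT' lines in engine output")
    return scores


def parse_docking_output(output_text: str, result_id: str = "pose") -> DockingResult:
    """Parse scored multi-MODEL PDBQT engine output into a DockingResult.

    Poses are re-sorted by score (stable) and re-ranked from 1, so the result
    invariant holds even for an engine emitting modes out of order.
    """
    scores = parse_scores(output_text)
    with tempfile.NamedTemporaryFile(
        "w", suffix=".pdbqt", delete=False
    ) as fh:
        fh.write(output_text)
        tmp = fh.name
    try:
        models = read_models(tmp, format="PDBQT")
    finally:
        Path(tmp).unlink(missing_ok=True)
    if len(models) != len(scores):
        raise ParseError(
            f"engine output has {len(models)} pose blocks but "
            f"{len(scores)} score lines"
        )
    order = sorted(range(len(scores)), key=lambda i: scores[i])
    poses = tuple(
        (models[i], float(scores[i]), rank)
        for rank, i in enumerate(order, 1)
    )
    return DockingResult(poses=poses)


def run_docking(
    executable,
    receptor_file,
    ligand_file,
    box: BoxSpec,
    seed: Optional[int] = None,
    out: Optional[Path] = None,
    extra_args: Sequence[str] = (),
    timeout: Optional[float] = None,
) -> DockingResult:
    """Invoke the external engine for one receptor/site and parse its output.

    The subprocess gets the engine-convention flag set (receptor, ligand,
    center_*/size_*, out, seed). stdout/stderr are captured verbatim into the
    result log; a missing executable or nonzero exit raises
    :class:`EngineError` carrying the log, with no partial result.
    """
    exe = shutil.which(str(executable)) or (
        str(Path(executable).resolve()) if Path(executable).is_file() else None
    )
    if exe is None:
        raise EngineError(f"docking executable not found: {executable}")
    for f, what in ((receptor_file, "receptor"), (ligand_file, "ligand")):
        if not Path(f).is_file():
            raise EngineError(f"{what} file not found: {f}")
    out_path = Path(out) if out is not None else Path(
        tempfile.mktemp(suffix=".pdbqt")
    )
    cmd = [
        exe,
        "--receptor", str(receptor_file),
        "--ligand", str(ligand_file),
        *box.cli_args(),
        "--out", str(out_path),
    ]
    if seed is not None:
        cmd += ["--seed", str(seed)]
    cmd += list(extra_args)
    try:
        proc = subprocess.run(
            cmd, capture_output=True, text=True, timeout=timeout
        )
    except subprocess.TimeoutExpired as exc:
        raise EngineError(f"docking engine timed out after {timeout}s") from exc
    log = proc.stdout + proc.stderr
    if proc.returncode != 0:
        raise EngineError(
            f"docking engine exited with status {proc.returncode}", log=log
        )
    if not out_path.is_file():
        raise EngineError("engine reported success but wrote no output", log=log)
    result = parse_docking_output(out_path.read_text())
    if out is None:
        out_path.unlink(missing_ok=True)
    return DockingResult(poses=result.poses, log=log)


def best_receptor(query_scores: Mapping[str, float]) -> BestReceptor:
    """Pick the receptor with the strongest (minimum) score for a ligand.

    Reports the margin to the runner-up; an exact tie at the minimum breaks
    deterministically by receptor name and is flagged ambiguous.
    """
    if not query_scores:
        raise InputError("empty receptor score map")
    items = sorted(query_scores.items(), key=lambda kv: (kv[1], kv[0]))
    best_id, best = items[0]
    if len(items) == 1:
        return BestReceptor(best_id, float(best), 0.0, False)
    runner_up = items[1][1]
    return BestReceptor(
        receptor_id=best_id,
        score=float(best),
        margin=float(runner_up - best),
        ambiguous=runner_up == best,
    )
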