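"""Drive an external docking engine (here: a stub) and pick the best receptor.

Shows the adapter contract end to end — box spec, subprocess invocation,
score parsing — against a stub executable, then runs best-receptor selection
on the published self-docking score sets of the two crystal ligands.
"""

import tempfile
from pathlib import Path

from gutdock.dockadapter import BoxSpec, best_receptor, run_docking
from gutdock.synthfix import SELFDOCK_SCORES, write_stub_engine

workdir = Path(tempfile.mkdtemp())
stub = write_stub_engine(workdir / "vina_stub.py")
ligand = workdir / "ligand.pdbqt"
ligand.write_text(
    "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00"
    "    +0.000 C \n"
)
box = BoxSpec(
    receptor_id="GCGR", site="orthosteric",
    center=(0.0, 0.0, 0.0), size=(22.0, 22.0, 22.0),
)
result = run_docking(stub, ligand, ligand, box, seed=1)
print(f"stub engine returned {len(result.poses)} poses, scores "
      f"{result.scores} (kcal/mol, lower = stronger)")

print("\nbest receptor per crystal ligand from the printed score sets:")
for name, scores in SELFDOCK_SCORES.items():
    pick = best_receptor(scores)
    print(
        f"  {name}: {pick.receptor_id} at {pick.score} "
        f"(margin {pick.margin:.1f} to the runner-up)"
    )
print("(both crystal ligands select their true receptor)")
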