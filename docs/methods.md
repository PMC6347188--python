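# Methods

This note records the models and procedures implemented in `gutdock`, the
parameters that matter, the numerical conventions, and what the synthetic
generators do and do not emulate.

## Ligand-density grid and steric-hindrance score

**Model.** Superposed poses of the endogenous peptides (all structures share
one template frame; the package never superposes anything itself) define a
ligand density on a regular Cartesian grid over the orthosteric site. Every
*heavy* atom of every pose increments the count of the cell containing it;
all atoms carry equal weight. Cells are half-open boxes
`[origin + i·s, origin + (i+1)·s)` per axis so each point maps to exactly one
cell; a point exactly on the upper grid boundary is assigned to the last cell
so no atom inside the bounding box is silently lost. The grid origin is
snapped down to the spacing lattice: cell boundaries sit at integer multiples
of the spacing, which makes binning invariant under translations by whole
cells and keeps a bounding-box-defining atom off the cell edges.

The grid splits into a **core** (cells with nonzero density) and a **shell**
(zero cells with a nonzero neighbour). The neighbourhood is 26-connected by
default and configurable to 6 or 18; the underlying procedure only says
"neighbouring grid points", so the choice is explicit and recorded here. The
shell is exposed for small-molecule sites but unused by default scoring.

A receptor model's **steric-hindrance score** is the number of core cells
containing at least one receptor heavy-atom *center* — cells are counted,
not atoms, and no atomic radii are used, mirroring the ligand binning rule.
A radius-aware variant is deliberately not implemented.

**Parameters.** `spacing` (Å, default 1.0 — the grid resolution of the
original procedure), `padding` (Å, default 2.0 — expands the ligand bounding
box so shell cells exist inside bounds), `connectivity` (6/18/26,
default 26), `margin` (Å) for deriving docking boxes from a core
(center = centroid of core-cell centers; size = core bounding box + 2·margin
per axis).

## Ensemble bookkeeping

`filter_by_steric` keeps the `⌊keep_fraction·N⌋` models with the lowest
steric scores (the production setting is half of a 3000-model homology
ensemble, or half of 2000 MD snapshots); ties at the cutoff break by model
id, so reruns are deterministic without a seed. `select_representatives`
takes the `k` most populous clusters (ties: lower mean energy, then lower
label) and returns each cluster's lowest-energy member (ties: model id).
Cluster labels and knowledge-based-potential energies are inputs — the
clustering and energy evaluation themselves are external to this package.

## Enrichment metrics

Scores are directional; docking energies default to lower-is-better, and
every metric is invariant under strictly monotone transforms at fixed
direction.

- **EF(f)**: with `n = max(1, ⌊f·N⌋)` top compounds holding `a` actives, the
  concentration form `(a/n)/(A/N)` is the default (EF(1) ≡ 1); the recall
  form `(a/A)/f` is available via an argument. Ties at the cutoff resolve in
  score order then id order.
- **ROC/AUC**: AUC is the probability a random active outranks a random
  decoy with ties counted ½ (Mann–Whitney with midranks); ROC points
  collapse tied scores into single steps, so the trapezoidal area equals the
  AUC exactly (asserted in tests).
- **BEDROC(α)**: the Truchon–Bayly definition via RIE, with midranks for
  ties; α = 20 (early-recognition weight on roughly the first 8 % of the
  list) is the reporting default. `bedroc_bounds` gives the closed-form
  minimum/maximum for a library shape and serves as an oracle for the
  perfectly front-loaded screen.

The degenerate libraries (no actives or no decoys) raise a dedicated
undefined-metric error rather than returning a number.

## Off-target rank–score analysis

Clinical T2DM-risk ranks are small integers: 1 = least disturbing to glucose
homeostasis, 0 = no clinical data; rank-0 drugs are always excluded from
statistics. Two published assignments for the reference beta-blockers ship as
fixtures (they disagree on the nebivolol/carvedilol order; one lists them
tied): the `fig3` assignment (carvedilol 1, nebivolol 2, labetalol 3,
atenolol 4, metoprolol 5, compound 15 → 0) is the default, `table3`
(nebivolol 1, carvedilol 1, labetalol 2, atenolol 3, metoprolol 4) is a
config/argument away.

`rank_score_correlation` averages replicate scores per
(drug, receptor, site), then correlates rank against score per
(receptor, site) over the shared ranked drugs (at least three required).
Pearson on the raw scores is the default — the published analysis plots
binding affinity against integer rank and reports a single coefficient per
panel — with Spearman available when only the ordering is trusted. A
positive coefficient means the clinically safest drugs dock strongest
(scores are negative energies, so safest ⇔ lowest score).

**Combined ranking** (the merge rule was an open design choice): references
are ordered by clinical rank (name tie-break) and the query is inserted at
position `p` = number of references with strictly better (lower) mean score
across all (receptor, site) keys; an exact tie resolves toward the
reference. `p = 0` yields the reserved rank 0 — the published slot for a
query with no clinical data that out-scores every reference — with the
references keeping ranks 1..n; otherwise ranks run 1..n+1 sequentially.

`compare_query` emits the comparison-chart content as a plain table
(mean ± sample standard deviation across replicates per key, zero for a
single replicate) and requires no plotting backend.

## Docking adapter

The engine is strictly external and optional; nothing in the package
implements or modifies a scoring function. The adapter passes the
engine-convention flags (`--receptor --ligand --center_* --size_* --seed
--out`), captures stdout/stderr verbatim, fails atomically on nonzero exit,
parses `REMARK VINA RESULT` lines (a malformed result line is an error
naming its line number), and re-sorts modes by score with ranks re-assigned
from 1 so the result invariant holds for engines emitting modes out of
order. `best_receptor` returns the minimum-score receptor with its margin to
the runner-up; exact ties break by receptor name and are flagged ambiguous.
Engine defaults (exhaustiveness, modes) are not hard-coded; box specs are
config values, seedable from `derive_box` output.

## Structure I/O conventions

PDB goes through gemmi. PDBQT (AutoDock dialect) has its own fixed-column
reader/writer because the format stores an AutoDock atom type and partial
charge where PDB keeps the element and charge; AutoDock types map back to
elements (`A`→C aromatic, `OA`→O, `HD`→H, ...), and torsion-tree records
(ROOT/BRANCH/TORSDOF) are ignored. Hydrogen detection uses the element field
when present, else the first alphabetic character of the atom name —
wild-type PDB files often omit the element column — and deuterium counts as
hydrogen. Alternate locations keep the highest-occupancy conformer.
Pose RMSD is heavy-atom, positional (i-th against i-th) and applies no
superposition: poses are compared in the shared receptor frame, as in
self-docking validation. Symmetry-aware atom correspondence is deliberately
not implemented; for symmetric ligands the positional value is an upper
bound on the symmetry-corrected one.

## Synthetic data: what it emulates, and what it does not

- `gen_toy_complex` emulates a superposed peptide ensemble as uniform atom
  clouds in a spherical pocket, and a receptor that intrudes into exactly
  `receptor_intrusion` distinct core cells (atoms at cell centers) with its
  remaining atoms outside the grid. The planted score is exact by
  construction, which is what makes it an oracle. It does not emulate
  bonded geometry, residue structure, or partial cell occupancy by atomic
  radii — passing tests show the counting machinery is exact, not that the
  1 Å resolution is optimal for real loops.
- `gen_scored_library` draws active scores from N(−separation·σ, σ) and
  decoy scores from N(0, σ) (defaults: 10/500 compounds, σ = 1,
  separation 2 — a strongly enriched screen with AUC ≈ Φ(separation/√2) ≈
  0.92, in the range of the reported well-performing models). Real screens
  have heavier-tailed, multimodal score distributions; the generator is for
  metric validation, not docking realism.
- `gen_score_matrix` plants the *sample* Pearson coefficient exactly by
  mixing the standardized rank vector with standardized orthogonalized
  noise: `score ∝ ρ·z_rank + √(1−ρ²)·z_noise`. At five drugs the sample
  correlation estimator is visibly biased for a merely
  population-calibrated generator (≈ −0.017 at ρ = 0.9), so exact-sample
  planting was chosen as the generator's semantics: recovery studies then
  test the analysis path, not the estimator's small-n bias. `noise_sigma`
  (default 0.6) scales the score spread around a −8 kcal/mol baseline.

All generators take a mandatory integer seed and are bit-reproducible.

## Problem sizes and numerical choices

The test suite and the acceptance script use the pipeline's native sizes
where they are small (3000-model ensembles, 510-compound libraries,
5-drug/5-receptor/2-site matrices) and trim only the brute-force oracle
comparisons (toy grids ≤ 20³, 100 complexes; 1000 random libraries of
N ≤ 100; 200 replicate correlation matrices), which keeps exhaustive
enumeration exact and the whole run in seconds to a couple of minutes.
Monte-Carlo assertions use 3 standard errors of the replicate mean.
Oracle-equivalence assertions use 1e-9 absolute tolerance; closed-form
identities use 1e-12.

## Known limitations

- The steric score treats atoms as points; a receptor atom just outside a
  core cell contributes nothing regardless of its radius.
- Correlations over five drugs have wide confidence intervals; the package
  reports coefficients, not significance.
- The combined-ranking merge rule is one defensible choice among several;
  it is deterministic and documented above, but not uniquely implied by the
  published table.
- The PDBQT writer emits a minimal dialect (atom records only) sufficient
  for round-tripping poses, not a full AutoDock preparation.
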