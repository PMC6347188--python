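# gutdock

Docking post-processing for off-target studies on class B GPCRs (the gut
hormone receptors GCGR, GIPR, GLP1R and their relatives VIPR1 and PAC1R).
The package is aimed at structural bioinformaticians who build receptor-model
ensembles, validate them by virtual screening, and ask whether a drug's
docking scores across a receptor panel track a clinical outcome — here, the
risk that a beta-blocker disturbs glucose homeostasis and induces type 2
diabetes.

It provides four computational stages, usable separately or as a pipeline:

1. **Steric-hindrance filtering** (`gutdock.stericgrid`, `gutdock.ensemble`).
   The orthosteric peptide pocket is discretized on a Cartesian grid
   (spacing 1 Å); every heavy atom of the superposed endogenous-peptide
   poses is binned with equal weight, giving a ligand density. Cells with
   nonzero density form the *core*; zero cells adjacent to the core form a
   *shell*. A receptor model's steric score is

   S(model) = #{ core cells containing ≥ 1 receptor heavy atom },

   so models whose extracellular loops collapse into the pocket score high
   and are discarded (e.g. the worse half of a 3000-model ensemble). The
   lowest-energy member of each of the *k* largest clusters is then selected
   for screening.
2. **Enrichment metrics** (`gutdock.vsmetrics`). For an active/decoy score
   list (by default 10 actives, 500 decoys): EF at 1/5/10 % in the
   concentration form (a/n)/(A/N), the ROC curve, AUC as the tie-aware
   Mann–Whitney probability, and Truchon–Bayly BEDROC(α = 20).
3. **Off-target rank correlation** (`gutdock.offtarget`). Pearson (or
   Spearman) correlation between a drug's clinical T2DM-risk rank
   (1 = least disturbing, 0 = no data, excluded) and its docking score per
   receptor and binding site; combined clinical+docking rankings with a
   reserved rank 0 for an unranked query that out-scores every reference;
   query-vs-reference comparison tables with replicate dispersion.
4. **External docking adapter** (`gutdock.dockadapter`). Invocation contract
   and score parsing for an AutoDock-VINA-compatible engine, plus
   best-receptor selection. No engine is bundled; a stub executable
   (`gutdock.synthfix.write_stub_engine`) exercises the full contract.

`gutdock.structio` reads/writes PDB (via gemmi) and the AutoDock PDBQT
dialect, and computes superposition-free heavy-atom pose RMSD.
`gutdock.synthfix` generates all synthetic inputs (toy pocket complexes with
a known planted steric score, planted-enrichment libraries,
planted-correlation score matrices) and packages the clinical rank fixtures.

## Worked example

```python
from gutdock import (ModelRecord, filter_by_steric, grid_regions,
                     steric_score, enrichment_report)
from gutdock.synthfix import (ToyComplexSpec, gen_toy_complex,
                              PlantedEnrichmentSpec, gen_scored_library)

toy = gen_toy_complex(ToyComplexSpec(seed=105, receptor_intrusion=5))
core, shell = grid_regions(toy.grid)
print(len(core), steric_score(toy.grid, toy.receptor, core).score)
# 137 5   -> 137 ligand-occupied cells; this receptor intrudes into 5 of them

lib = gen_scored_library(PlantedEnrichmentSpec(separation=2.0, seed=2019))
r = enrichment_report(lib)
print(f"{r.auc:.3f} {r.bedroc_alpha20:.3f} {r.ef1:.1f}")
# 0.965 0.771 40.8  -> a strongly enriched screen: a random active ranks
# above a random decoy 96.5 % of the time, and the top 1 % of the list is
# 40.8x richer in actives than the library (ceiling 51 for 10/510)
```

The `examples/` directory holds one short narrative script per capability
(`steric_filtering.py`, `enrichment_metrics.py`, `offtarget_correlation.py`,
`docking_adapter.py`); each prints the numbers above-style with a line on
what they mean. A thin CLI mirrors the pipeline
(`gutdock density-score | filter-ensemble | select-models | enrich | dock |
offtarget-corr | compare-query | simulate`).

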