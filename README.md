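# cnstriage

Integrative CNS drug-repurposing triage pipeline. Starting from regulator
activity matrices, docking-affinity grids, physicochemical descriptor tables
and molecular-dynamics trajectories, it identifies differentially active
regulators, filters drug–target pairs by binding affinity, profiles
blood–brain-barrier suitability, computes trajectory stability metrics, and
combines everything into a gated, ranked candidate report.

## Modules

| Module | Purpose |
| --- | --- |
| `cnstriage.simulate` | Seeded synthetic inputs for every stage (activity matrices with planted signal, QC count tables, docking grids with planted binders, geometric trajectories with drift/escape) |
| `cnstriage.regulators` | Cell QC, per-cluster Welch z statistics, weighted Stouffer combination, Benjamini–Hochberg FDR, dual significance gate, cohort-set intersection |
| `cnstriage.docking` | Affinity-threshold triage (pass iff affinity ≤ −7 kcal/mol, inclusive), aggregate ranking, cross-engine Spearman concordance |
| `cnstriage.cns` | Linear logBB model (0.152·LogP − 0.0148·TPSA + 0.139), five permeability bins, P-gp efflux rule (LogP > 4 ∧ TPSA < 75), safety/toxicity lipophilicity windows, optional RDKit descriptor recomputation |
| `cnstriage.trajectory` | Kabsch superposition, RMSD series, Shrake–Rupley SASA (Fibonacci lattice, exactly rigid-motion invariant via a principal-axes canonical frame), geometric H-bond detection (3.5 Å / 120°), mean ± SD summaries |
| `cnstriage.ranking` | Pharmacokinetic gates with recorded exclusion reasons, policy-driven stable sort, JSON/TSV reports with a shipped schema |
| `cnstriage.pipeline` / `cnstriage.cli` | Strictly validated YAML config, provenance logging with checksums, end-to-end orchestration |
| `cnstriage.fixtures` | Packaged reference tables (docking grid, descriptor table, MD stability summary) with as-printed provenance |

Notable conventions (documented in the module docstrings):

* Docking pass rule is **affinity ≤ threshold with inclusive equality**;
  "stronger than −7" refers to binding strength, not algebraic order.
* logBB bins are inclusive on the upper category; the efflux rule uses
  strict inequalities; window bounds are inclusive.
* Computed BBB-permeability = bin Moderate or better (logBB ≥ −0.3). The
  fixture's printed flag column disagrees for exactly one drug (Olaparib)
  and is retained as printed.
* The H-bond criterion is the stated fixed distance+angle cutoff pair
  (donor–acceptor distance, angle at the hydrogen); a distance–angle
  coupled mode is available as an alternative.

## CLI

```sh
cnstriage simulate activity --seed 1 --out out/          # also: counts, docking, trajectory
cnstriage call-ders --activity out/activity.tsv --meta out/activity_meta.tsv \
    --fdr 0.05 --min-score 1.5 --out out/ders.tsv
cnstriage dock-filter --targets APP,ZEB2,PAX6,ETV6,ST18 --threshold -7 \
    --min-pass 1 --out out/candidates.tsv
cnstriage cns-profile --out out/profiles.tsv
cnstriage traj-metrics --traj out/trajectory.pdb --meta out/trajectory_meta.tsv \
    --probe 1.4 --points 960 --dist 3.5 --angle 120 --out out/
cnstriage rank --out out/
cnstriage run-all --config config.yaml --seed 1 --out out/
```

`dock-filter`, `cns-profile` and `rank` default to the packaged fixtures
when no input file is given. `run-all` executes every stage, writes a
`provenance.jsonl` with config echoes and output checksums, and is
deterministic under a fixed seed.

## Tables

All tabular I/O is TSV (UTF-8, header row); CSV is accepted on read, and
Unicode minus (U+2212) is normalized before numeric parsing.
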