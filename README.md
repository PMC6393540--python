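# coopfold

Reusable pipeline for three biophysical analyses of a toxin–antitoxin-style
system in which an antitoxin dimer pair binds its DNA operator cooperatively
and a toxin carries a disordered N-terminal tail:

- **`coopfold.itc_binding`** — cooperative tri-molecular binding model
  (2 dimer + 1 duplex ⇌ complex, macroscopic K_A in M⁻²): exact speciation
  by bracketed root finding, a sequential two-site contrast model,
  closed-cell ITC injection simulation with perfusion dilution, and
  least-squares isotherm fitting on (log₁₀ K_A, ΔH, offset) with
  multi-start, asymptotic errors and ΔG = −RT ln K_A at 25 °C.
- **`coopfold.saxs_analysis`** — iterative Guinier fitting, dimensionless
  Kratky transform with the analytic globular (peak (√3, 3/e)) and Debye
  random-coil (asymptote 2) reference laws, peak finding and foldedness
  classification, exact coarse-grained Debye profiles, self-avoiding
  flexible-tail conformer pools, MultiFoxs-style multi-state ensemble
  fitting (NNLS per subset, exact enumeration or beam search), weighted Rg
  distributions, and Porod volume / MW estimates.
- **`coopfold.structure_metrics`** — PDB reading (Biopython backend),
  Kabsch superposition with reflection guard, backbone RMSD with residue
  maps for cross-protein comparisons, centroid distances, inter-domain
  rotation angles, deterministic Shrake–Rupley SASA (golden-spiral points),
  buried surface area, and sequence net charge.
- **`coopfold.synthetic_data`** — seeded generators for every input:
  ITC isotherm CSVs, globular bead bodies, rigid-body-plus-tail ensembles
  with noisy mixture curves, toy structures with exact known transforms,
  and the operator sequence variant table as FASTA. Every fixture ships a
  ground-truth sidecar JSON.
- **`coopfold.io_cli`** — SAXS `.dat` / ITC CSV / JSON report formats, run
  configuration with config-hash provenance, and the `coopfold` CLI.

## CLI

```sh
coopfold itc simulate --params params.json --protocol protocol.json --noise 0.1 --seed 7 -o iso.csv
coopfold itc fit iso.csv -o fit.json
coopfold itc speciate --ka 3e13 --duplex 5e-6 --ratios 0:0.1:4
coopfold saxs guinier curve.dat
coopfold saxs kratky curve.dat [--rg R --i0 I]
coopfold saxs profile model.pdb --q 0.005:0.001:0.5
coopfold saxs ensemble --rigid body.pdb --tail 22 --n 1000 --seed 1 --exp curve.dat --max-states 4
coopfold struct rmsd a.pdb b.pdb --sel-a A:4-99:backbone --sel-b A:4-99:backbone [--map pairs.tsv]
coopfold struct comdist m.pdb --sel-a A:35-45 --sel-b B:35-45
coopfold struct rot c1.pdb c2.pdb --align A --measure B
coopfold struct bsa m.pdb --part-a A,B --part-b C,D
coopfold fixtures make --spec spec.json -o out/
```

Selections are `chain[,chain]:start-end[,start-end][:atomset]` with atom
sets `backbone`, `ca`, `heavy`, `all` or explicit `N+CA+C`.

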