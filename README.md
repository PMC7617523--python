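# ppi-missense

Structure-based prediction of missense-variant damage at protein–protein
interfaces.

Most variant-effect predictors assess a substitution on a single protein
chain, so a surface variant that folds fine in the monomer but wrecks a
binding site is called tolerated. `ppi-missense` takes the 3D
coordinates of a **complex** (experimental or modelled, PDB format) and
asks the question at the interface: it maps which residues of the query
chain lose solvent accessibility to the partner chains, rebuilds the
mutant side chain in place, and scans a catalogue of interchain
structural-damage features. It is aimed at structural bioinformaticians
and variant-curation pipelines that have a complex structure in hand and
want a mechanistic, feature-by-feature call rather than a bare score.

## Method in brief

* **Interface map.** Per-residue relative solvent accessibility (RSA,
  Shrake–Rupley SASA over the Tien et al. maxima) is computed for the
  monomer and the full assembly. A residue is an interface residue when
  RSA_monomer − RSA_complex ≥ 5, and is classed by the 9 % threshold:
  *core* (RSA_m ≥ 9 > RSA_c), *rim* (both ≥ 9), *support* (both < 9).
* **Mutant model.** Side chains within 5 Å of the site are stripped and
  greedily repacked on a fixed backbone from a rotamer library, starting
  from the wild-type conformations (minimal perturbation, fully
  deterministic).
* **Damage features.** 15 interchain features: H-bond / salt-bridge /
  disulfide breakage and formation (heavy-atom cutoffs 3.5 / 4.0 / 2.5 Å,
  +1 Å model allowance on the first two), charge replaced / switched /
  unbalanced, Gly/Tyr/Trp replaced, Pro introduced, Gly in a bend,
  steric clash (vdW overlap ≥ 0.77 Å), and interfacial cavity change
  (≥ 70 Å³). Bond and charge features apply on core/support residues
  only.
* **Verdict.** *Damaging* if any triggered feature affects two or more
  interchain residues (the site plus at least one partner interface
  residue); *neutral* otherwise; *not_interface* when the site loses no
  accessibility on complex formation.

The package also ships the evaluation arithmetic used to benchmark such
predictors: confusion-matrix panels (sensitivity, specificity, TPR, FPR,
TPR/FPR, accuracy, MCC), two-sided ΔΔG ≥ 1.5 kcal/mol binarisation for
energy-based methods, and McNemar's paired test.

## Worked example

Generate a toy dimer with an engineered interchain Lys–Glu salt bridge
at 3.0 Å, bury the lysine to interface-core level, and remove it:

```bash
python - <<'PY'
from ppi_missense.fixtures import make_pocket_dimer
from ppi_missense.structure_model import write_structure
s, site = make_pocket_dimer("LYS", "GLU", 3.0, "core")
write_structure(s, "pocket.pdb")   # site is chain A, residue 4
PY
ppi-missense predict --pdb pocket.pdb --chain A --position 4 --wt K --mut A --format text
```

prints (abridged):

```
Variant A/LYS4ALA
Verdict: damaging
Interface category: core (RSA monomer 84.1%, complex 1.7%)
Partner chains: B, C
Rationale: 3 structural damage feature(s) affect two or more interchain residues: interface_hbond_breakage, interface_salt_bridge_breakage, interface_charge_replaced
Features:
  [TRIGGERED] interface_hbond_breakage — hbond lost: NZ(A4)-O(C72) at 3.36 A; ...
  [       ok] interface_hbond_formation
  [TRIGGERED] interface_salt_bridge_breakage — salt_bridge lost: NZ(A4)-OE1(B14) at 3.91 A; ...
  [TRIGGERED] interface_charge_replaced — charged LYS replaced by neutral ALA
  ...
```

Reading this: the lysine was exposed in the monomer (RSA 84 %) and buried
in the complex (1.7 %), i.e. an interface-core residue. Replacing it
with alanine severs the engineered salt bridge to Glu B14 and the
ammonium's hydrogen bond to a partner carbonyl, and removes a charge —
three features each implicating the site plus partner-chain residues, so
the variant is called damaging. `--out report.json` writes the same
content as schema-versioned JSON (byte-identical across runs);
`ppi-missense interface --pdb pocket.pdb --chain A` dumps the per-residue
interface table as TSV.

The library surface mirrors the CLI: `parse_structure`, `map_interface`,
`build_mutant`, `evaluate_features`, `predict`, `render_report`, plus
`compute_metrics` / `classify_ddg` / `mcnemar_test` for benchmarking.

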