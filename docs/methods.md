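# Methods

`ppi-missense` predicts whether a missense substitution damages a
protein–protein interface, using only the 3D coordinates of the complex.
This note records the model, its parameters, the numerical choices, and
what the synthetic test fixtures do and do not establish.

## Pipeline

Given a multi-chain structure and a variant (chain, residue number,
wild-type and mutant amino acid):

1. **Interface mapping.** Relative solvent accessibility (RSA) of every
   query-chain residue is computed twice: on the extracted monomer and on
   the full assembly (all partner chains occluding simultaneously, so
   multimer interfaces are handled in one pass). A residue is an
   interface residue when it loses ≥ 5 percentage points of RSA on
   complex formation, and is categorised by the 9 % buried/exposed
   threshold: **core** (exposed → buried), **rim** (exposed → exposed),
   **support** (buried → buried). Boundary semantics: the exposed test
   (≥ 9 %) and the interface test (≥ 5) are inclusive; the buried test
   (< 9 %) is exclusive. Variants at non-interface residues return
   `not_interface` without further work.
2. **Mutant modelling.** The wild-type side chain and every side chain
   with a heavy atom strictly closer than 5 Å to the site (any chain) are
   removed; the mutant side chain is introduced from ideal internal
   coordinates and the shell is repacked on a frozen backbone.
3. **Feature evaluation.** A 15-feature catalogue of interchain damage
   signals is evaluated by comparing the mutant against a repacked
   wild-type baseline (below).
4. **Verdict.** The variant is damaging when at least one triggered
   feature affects two or more interchain residues: its implicated
   residue set, restricted to residues that are interface residues of
   their own chain, must contain the site plus at least one more residue.

## Solvent accessibility

Shrake–Rupley sphere sampling on a deterministic Fibonacci lattice
(960 points per atom, water probe 1.4 Å), heavy atoms only, Bondi van der
Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å). Residue SASA is
normalised by the Tien et al. theoretical maximum accessible areas, as a
single swappable table. No random numbers are involved, so SASA is
bit-reproducible. The lattice discretisation gives ≤ 1 % error against
closed-form sphere and two-sphere-cap areas; per-residue values vary by
up to ~1.5 % under rigid-body motion (the structure total by ≤ 0.5 %).
RSA may exceed 100 % in extended conformations and is not clamped;
occlusion can only remove area, so complex RSA is clipped at monomer RSA
to suppress sub-0.1 % sampling noise on the buried side.

Partner attribution recomputes the assembly SASA with each partner chain
removed; a chain is credited as a partner when its removal restores at
least 1 percentage point of the residue's RSA.

## Side-chain repacking

The bundled packer is a deterministic greedy search over a compact
backbone-independent rotamer library (staggered χ wells, perpendicular/
in-plane wells for planar groups; ≤ 81 rotamers per residue type), with
side chains built by natural-extension (NeRF) from ideal bond lengths and
angles. Scoring per rotamer:

* squared van der Waals overlap beyond a 0.4 Å tolerance (penalty);
* a small reward (0.3 per contact) for N/O pairs at hydrogen-bonding
  distance (2.4–3.6 Å) and a larger one (0.7) for oppositely charged
  side-chain groups within salt-bridge range, so that among clash-free
  rotamers the bond-restoring one wins deterministically;
* S–S pairs at disulfide distance (≤ 2.5 Å) are treated as covalent, not
  clashing.

Packing is **minimal-perturbation**: every shell residue whose type is
unchanged starts from its wild-type conformation and is only moved when a
library rotamer scores strictly better. The mutated site starts empty.
Residues are visited in order of increasing distance from the site,
sweeps repeat to convergence (≤ 3), and ties keep the incumbent — no
randomness anywhere, so identical inputs give bit-identical models. A
residue that cannot be placed without residual overlap keeps its
best-available rotamer and is flagged strained, never dropped.

The backend is pluggable: any callable honouring the contract (backbone
bit-identical, single-position sequence change, deterministic) can stand
in for the built-in packer.

## Feature catalogue

All wild-type-versus-mutant comparisons use a **repacked wild-type
baseline** — the deterministic self-mutant of the same site — so that
differences reflect the substitution, not side-chain rebuilding; a
self-mutation therefore triggers nothing by construction. Identity
features take their implicated partner contacts from the raw input
coordinates.

| # | feature | definition | gating |
|---|---------|------------|--------|
| 1/2 | H-bond breakage / formation | donor–acceptor heavy-atom pair ≤ 3.5 + 1.0 Å spanning chains, involving the site, lost/gained vs baseline | core/support |
| 3/4 | salt-bridge breakage / formation | oppositely charged side-chain groups ≤ 4.0 + 1.0 Å | core/support |
| 5 | disulfide breakage | interchain SG–SG ≤ 2.5 Å lost (no allowance) | core/support |
| 6 | charge replaced | charged wild type (D/E/K/R/H) → neutral mutant | core/support |
| 7 | charge switch | wild-type and mutant side chains of opposite sign | core/support |
| 8 | unbalanced charge introduced | neutral → charged with no opposite-sign partner atom within the effective salt-bridge cutoff | core/support |
| 9–11 | Gly / Tyr / Trp replaced | interface identity features | any |
| 12 | Pro introduced | any → Pro | any |
| 13 | Gly in a bend | feature 9 and CA-trace curvature > 70° at the site | any |
| 14 | steric clash | new interchain heavy-atom pair with vdW overlap ≥ 0.77 Å | any |
| 15 | cavity alteration | interfacial solvent-excluded void changes by ≥ 70 Å³ | any |

The +1 Å model allowance on H-bond and salt-bridge cutoffs accommodates
modelled and lower-resolution structures. Bond detection is heavy-atom
distance only (typical X-ray inputs lack hydrogens); there is no angular
term, a documented divergence from hydrogen-aware detectors. A
donor–acceptor pair whose atoms form a salt bridge is reported once, as
the salt bridge. Cysteine SG is not a hydrogen-bond donor here: thiol
donor geometry cannot be judged without hydrogens, and disulfides are
detected separately. Histidine counts as positively charged because its
protonation state is unknowable from heavy atoms — this maximises the
sensitivity of the charge features.

Bond/charge features (1–8) are evaluated only on core and support
residues; on the solvated rim they are recorded as inapplicable. This
gating reflects where buried chemistry matters.

**Cavity metric.** A 1 Å grid is laid over the assembly; a voxel is empty
when outside every van der Waals sphere, and solvent-swept when within
one probe radius (1.4 Å) of a probe-admissible position connected to the
box boundary. Empty, unswept voxels within 6 Å of at least two chains
constitute the interfacial solvent-excluded void: enclosed pockets and
crevices too narrow for water. This was chosen over an enclosed-only
flood fill, which is fragile at grid resolution (a single-voxel crack
empties a cavity) and blind to packing defects that never fully close.

**Bend state.** The DSSP-style bend criterion: the angle between the
CA(i−2)→CA(i) and CA(i)→CA(i+2) directions exceeds 70°. Chain termini
(insufficient flank) report not-bent.

## Decision rule

The damaging rule — at least one triggered feature affecting two or more
interchain residues — is applied to each feature's implicated set: the
site plus the partner residues participating in the lost/gained
interaction, clash pair, or (for identity features) any partner residue
with a heavy atom within 5 Å of the wild-type site. The set is
restricted to interface residues before counting, so a feature whose
partners lose no accessibility cannot carry a verdict. This reading
makes the identity features usable (a replaced interface glycine with one
interface contact qualifies) while requiring genuine interchain
involvement. Multi-feature variants report every triggered feature; the
verdict is their disjunction.

## Evaluation utilities

`compute_metrics` produces sensitivity, specificity, TPR, FPR, TPR/FPR
(∞ when FPR = 0), accuracy and MCC (0 when a marginal factor vanishes)
from a confusion matrix. Energy-based predictors are binarised with the
two-sided |ΔΔG| ≥ 1.5 kcal/mol rule (boundary damaging; cutoff
configurable). McNemar's paired test uses the exact two-sided binomial
when the discordant count is below 25, otherwise the χ² approximation on
1 df with optional continuity correction; zero discordance yields p = 1.

## Synthetic fixtures

All test structures are generated: ideal-geometry peptides (extended
strand φ/ψ −139/135°, helix −57/−47°, ω trans, Engh–Huber-style bonds
and angles) with side chains built from the same templates the packer
uses, so engineered contacts (hydrogen bond, salt bridge at 3.0 Å,
disulfide at 2.05 Å, clash) are exact by construction. Controlled burial
places the variant site under a partner "lid" of parallel strands; core
burial adds an under-slab and a ring of vertical poly-glycine columns (a
separate scaffold chain) around the side-chain axis, burying any side
chain while keeping the contact axis open and keeping lid residues
genuine interface residues of their own chain.

The labelled variant panel covers every catalogue feature with a trigger
case, neutral controls (self-mutations, a conservative Ile→Val swap in a
quiet pocket), a rim-gated control, and a far-from-interface case.
Where burying a polar or charged side chain necessarily hydrogen-bonds it
to the surrounding shell, the corresponding bond feature is part of that
entry's expectation — real interface variants behave the same way,
with single substitutions triggering several features at once.

What the fixtures do not emulate: real packing density (toy pockets are
crevice-rich, so the cavity signal is stronger than in crystal
structures), backbone relaxation, waters and ligands, electron-density
artefacts, and the conformational diversity of real rotamers. Passing
the panel shows the detectors and the decision rule are wired correctly
end to end, not that field performance matches any benchmark; the
benchmark arithmetic is validated separately against the reference
benchmark rates.

## Problem sizes

Panel structures run 35–175 residues; the full 18-entry panel evaluates
end-to-end in under a minute on one CPU, and the complete test suite in
about two. Assembly SASA is computed once per prediction and shared
between the query and partner interface maps.

## Known limitations

* PDB input only; first model of multi-model files; altlocs resolved to
  highest occupancy at parse time.
* No hydrogen-aware bond geometry, no π-stacking/cation–π detection, no
  water-mediated bonds, no energies or ΔΔG estimation.
* The rotamer library is coarse (staggered wells); strained or unusual
  wild-type conformations are preserved by minimal-perturbation packing
  but cannot be *recovered* once a mutation displaces them.
* Five of the original method's twenty features are unpublished and
  therefore absent; the catalogue version string marks the set
  implemented, and the enum is open for extension.
* Interface categories near the 5 %/9 % thresholds are sensitive to the
  accessibility reference scale; the table is a single constant and can
  be swapped.
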