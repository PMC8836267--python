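# Methods

This note documents the models, parameters and design choices behind
melanostab, in the spirit of a methods appendix: what each procedure
assumes, which knobs matter, and what the synthetic-data tests do and do not
establish about real structures.

## Structure model and PDB conventions

Structures are flat residue lists with explicit atom-serial bonds; parsing
and writing go through gemmi.  Conventions:

- **Author numbering is opaque and preserved verbatim.**  No renumbering is
  ever applied, so positions like C40 or G59 stay addressable exactly as
  published (whether or not the source numbering counts a signal peptide is
  irrelevant to the analyses, which only ever address residues by number).
- **Metal bonds are explicit.**  Zinc–NE2 coordination is carried as PDB
  `CONECT` records and survives read→write round-trips.  Zincs are tagged
  ZnA, ZnB, … in atom-serial order.
- **Altlocs**: the highest-occupancy conformer per atom name is kept (with a
  warning); all downstream geometry is single-conformer.
- **Hydrogens** are retained when present; every heavy-atom operation works
  without them.
- **B-factor export**: per-residue scores overwrite the B-factor of every
  atom of the scored residue; unscored residues get 0.00, which is neutral
  under common viewer color ramps.
- Coordinates round-trip to the PDB precision of 3 decimals; serials beyond
  99,999 are a hard error rather than a silent wrap.

## Stability screen

### Standardization transform

ΔΔG (kcal/mol, positive = destabilizing) is mapped to the fraction of
protein in the unfolded state by the two-state Boltzmann occupancy

    f(ΔΔG) = 1 / (1 + exp(−ΔΔG / RT)),   RT = 0.0019872 × T kcal/mol

with T = 298.15 K by default.  This is the canonical monotone [0, 1]
standardization for a two-state folding equilibrium: f(0) = 0.5,
f(x) + f(−x) = 1, and destabilizations of ~6 kcal/mol already give
f ≥ 0.9999.  Note that no monotone transform can simultaneously send a
smaller ΔΔG to a *larger* unfolding fraction than a bigger ΔΔG; published
tables that pair values non-monotonically (e.g. through per-snapshot
averaging or rounding elsewhere in their provenance) cannot be reproduced
entry-by-entry by any single transform, and this package does not try.

### Foldability

For each residue, the 19 possible substitutions are enumerated and

    foldability = Σ_s  w_s · f(ΔΔG_s)     (s over the 19 substitutions)

with severity weights w_s ∈ [0, 1], all 1.0 by default so the ceiling is
exactly 19.  Weights are configurable per substitution (key "CS") or per
mutant letter (key "S") for users who want class-specific severities; no
canonical weight set ships with the package.

### Built-in ΔΔG engine

The engine is a deliberately transparent, deterministic scoring function —
an orderable surrogate, not a physical potential, and its absolute values
are not comparable to semi-empirical force-field outputs (which can instead
be imported as a table and standardized identically).  Terms:

    ΔΔG = c_h·B·[(H_wt − H_mut)/ΔH_max]₊  +  c_v·B·|V_mut − V_wt|/ΔV_max
        + c_ss·n_bridges_broken  +  c_g·B·[wt = Gly]  +  c_p·B·[mut = Pro]

- **Burial** B = min(1, N₁₀/20), where N₁₀ counts other residues with any
  heavy atom within 10 Å of the mutated residue's CB (CA for Gly).  Burial
  scales all environment terms, so fully exposed positions score ≈ 0.
- **Hydrophobic mismatch**: Kyte–Doolittle hydropathy H, positive part only
  (burying a polar residue where a hydrophobic one was); ΔH_max = 9.0.
- **Packing volume**: standard side-chain van-der-Waals volumes V (Å³),
  ΔV_max = 120 Å³.
- **Disulfide loss**: n_bridges_broken counts detected bridges containing
  the position when a Cys is substituted by a non-Cys.
- Coefficients: c_h = 2.0, c_v = 2.0, c_ss = 4.0, c_g = 2.0,
  c_p = 2.5 kcal/mol.

### Critical threshold

A residue is *critical* when its foldability reaches the configured
threshold.  Conceptually the criterion is "foldability at the ceiling of
19", but under the two-state transform the unfolding fraction is strictly
below 1 for any finite ΔΔG, so a literal threshold of 19 is unattainable
from computed energies.  The default is therefore derived from the engine's
closed-form bounds: a bridge-forming cysteine is guaranteed
foldability ≥ 19·f(4.0) ≈ 18.978 by the disulfide term alone, while the
worst case without a bridge (a fully buried glycine) sums to ≈ 18.94.  The
default threshold 18.95 separates the two regimes with margin on both
sides; it is configurable for imported ΔΔG tables with different scales.

## Disulfide detection

Bridges are detected geometrically: all Cys SG–SG pairs within the cutoff
(default 2.5 Å; covalent S–S ≈ 2.05 Å) are sorted by distance and matched
greedily, so each cysteine joins at most one bridge and the result is
deterministic and order-independent.  Cysteines lacking an SG atom (the
normal state after an in-silico substitution) simply cannot match.  Domain
labels come from user-supplied residue intervals; a bridge spanning two
labeled intervals is labeled "other" with a warning, since no principled
assignment exists.

## Pose analysis

- **Sign convention**: binding energies are stored positive-favorable, the
  convention of the docking tables this mirrors, and
  K_d = exp(−E/RT) × 1 M at standard state (T default 298.15 K).  When a
  mean energy is converted, Jensen's inequality makes the result a lower
  bound of the mean per-pose K_d — the two agree only to within
  pose-averaging spread.
- **Validity**: at least one flagged aromatic-ring oxygen strictly closer
  than 4.0 Å to a zinc, plus the orientation surrogate: both ring oxygens
  closer to the Zn–Zn midpoint than the ligand heavy-atom centroid.
  "Oriented towards the active site" is qualitative in the source analyses;
  this surrogate is the simplest testable operationalization and is the
  package's own choice.
- **RMSD and clustering**: poses are assumed already superposed on the
  receptor, so pose–pose heavy-atom RMSD involves no fitting (a Kabsch
  utility is provided separately for structure comparison).  Clustering is
  greedy leader clustering on the energy-sorted list (ties broken by
  pose_id): the best-energy pose seeds a cluster, each pose joins the first
  representative within the cutoff (default 5.0 Å) or founds a new one.
  Representatives are therefore pairwise ≥ cutoff apart and the outcome is
  input-order independent.
- **Fingerprint criteria** (conventional values; the source analyses name
  interactions but no thresholds): hydrogen bond = N/O pair ≤ 3.5 Å with
  best D–H···A angle ≥ 120° when hydrogens exist, distance-only otherwise;
  hydrophobic = apolar-carbon pair ≤ 4.0 Å, where "apolar" excludes carbons
  with an oxygen within 1.35 Å (carbonyl/carboxylate); π–π = aromatic
  side-chain ring centroid (His/Phe/Tyr/Trp) within 5.5 Å of the ligand
  ring centroid; generic contact radius 4.0 Å.

## Distance maps

Maps are computed over standard residues in CA mode (default; robust to the
side-chain truncation performed by the mutation operator) or min-heavy
mode.  Distances are rigid-motion invariant, so the entrywise difference of
two maps isolates conformational change.  "No structural fluctuation" is
operationalized as a named statistic — the fraction of residue pairs with
|Δd| above a threshold (default 2.0 Å) — because the underlying qualitative
judgement needs a testable form.  Snapshot input is multi-MODEL PDB with a
default stride of 0.1 ns.

## Synthetic structures

The generators produce exactly the geometry the analyses consume and
nothing more:

- **Cys mini-domain**: backbone on a coarse helical lattice (radius 10 Å,
  40°/residue, 2 Å rise — consecutive CA ≈ 7 Å).  Paired SG atoms sit at
  2.05 Å on the axis between their CA positions; unpaired SG atoms are
  placed radially and verified ≥ 6 Å from every other SG (generation fails
  loudly if a requested pairing cannot satisfy this).  The default fixture
  is 300 residues with the seven bridge pairings at positions 29/40, 41/61,
  52/95, 97/106, 109/118, 254/257, 286/299 and a glycine at 59, so the
  three OCA8 variants apply verbatim.
- **Zinc site**: ZnA/ZnB 3.3 Å apart (a conventional binuclear separation;
  any value in 3–4 Å behaves identically in the checks) with the bridging
  water midway and two NE2 tripods at 2.1 Å pointing into the −z
  half-space, leaving +z open as the substrate approach direction; six full
  imidazole rings are built behind the NE2 atoms and each Zn–NE2 pair gets
  a CONECT bond.
- **Ligand**: an idealized planar bicyclic template (1.39 Å aromatic
  bonds), two phenolic oxygens on the six-ring, a carboxylate on the
  five-ring.  Placement aligns the oxygen pair with the Zn–Zn axis and
  bisects along the approach normal until the nearest ring-oxygen-to-zinc
  distance meets the request (achieved within 0.05 Å over 1.8–8 Å; the
  solver lands on the ≥ side, so a pose requested exactly at a cutoff is
  excluded by the strict comparison).  Distances below 1.5 Å are refused as
  steric clashes.
- **Pseudo-trajectories**: i.i.d. Gaussian per-atom displacement of a
  reference structure (sd σ per coordinate), bit-identical for a fixed
  seed.  The mean 3-D displacement magnitude is σ·2√(2/π), which the tests
  verify by Monte Carlo.

What passing tests show — and what they do not: the fixtures guarantee
distances, not stereochemistry.  They establish that the detectors,
classifiers and aggregators implement their stated geometry and algebra
exactly, and that the screen's criticality logic recovers engineered ground
truth.  They do not establish that the built-in ΔΔG engine ranks real
mutations as a physical potential would, nor that real docking poses
produce the same fingerprints — for real structures, import external ΔΔG
tables and poses and rely on the standardization, aggregation and QC layers,
which are engine-independent.

## Numerical choices and degenerate inputs

- The logistic transform is evaluated with `scipy.special.expit`, avoiding
  overflow for any ΔΔG; values like f(77.6 kcal/mol) saturate to 1.0 in
  double precision.
- Identity substitutions are defined to have ΔΔG = 0 and are never
  enumerated by the screen.
- Greedy matchers (disulfides, clustering) break exact ties
  deterministically: by residue id for bridges, by pose_id for cluster
  seeds; criticality lists are reported in residue-number order.
- Distance matrices are symmetrized (½(M + Mᵀ)) to remove floating-point
  asymmetry before validation.
- Empty structures, residues missing required atoms, wild-type mismatches,
  topology mismatches between snapshots, and serial overflow all raise
  typed errors naming the offending entity rather than degrading silently.

## Problem sizes

The shipped defaults are desk-scale: the 300-residue fixture screens
(19 × 300 substitutions) in under a second, trajectories of 5–10 snapshots
cover the fluctuation statistics, and the full test suite runs in a few
seconds.  All generators scale linearly if larger synthetic systems are
wanted.

## Known limitations

- The built-in engine has no electrostatics, entropy or rotamer repacking;
  it is a surrogate for ordering and pipeline testing, with external tables
  as the route to quantitative energies.
- Pose clustering assumes a shared receptor frame; poses from different
  receptor superpositions must be aligned (e.g. with the Kabsch utility)
  before clustering.
- The orientation surrogate is centroid-based and can misjudge strongly
  bent ligands; it is exact for the planar template shipped here.
- mmCIF, assembly expansion and occupancy refinement are out of scope;
  input is single- or multi-MODEL PDB.
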