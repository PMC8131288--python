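# Methods

## What the converter does

`gmxnmr` reads the restraint save-frames of an NMR-STAR v3 deposition —
general distance (NOE) constraints, torsion-angle constraints, and RDC
constraints — and writes GROMACS include files plus a run-parameter
fragment.  Conversion is two-layered: an NMR identifier is first expanded
to the real atoms it denotes (pseudo-atoms such as `MB` are proton
groups), then each atom is renamed to the target force field's scheme
(Amber or Charmm).  The rules live in a plain-text table
(`src/gmxnmr/data/translations.tsv`) so users can extend them for other
force fields or non-standard residues; identifiers without a rule pass
through unchanged so that an unknown name surfaces later as a logged
topology miss, not a crash.

One deviation from a literal reading of the published rule table: the
shifted-proton rows for HG/HD/HE are printed twice with only the x₃ → x₂
member visible.  We encode the full pair (x₂ → x₁ *and* x₃ → x₂),
mirroring the explicitly printed HB pair.  Without the x₂ → x₁ member,
deposition names like `HG2` would collide with the shifted `HG3` target
and every restraint on an x₂ proton would fail to resolve in Amber-named
topologies — precisely the failure mode the translation layer exists to
prevent.

## Restraint construction choices

- **Units.** Depositions are in Å and degrees; conversion to nm happens
  exactly once, in `restraint_build`.  Energies use radians internally
  (force constants are per rad²).
- **Bounds.** r₀ and r₁ come from the deposited lower/upper bounds; a
  missing lower bound becomes r₀ = 0 (upper-bound-only NOEs are common);
  `(target ± tolerance)` depositions are converted to explicit bounds at
  parse time.  r₂ = r₁ + 0.1 nm by default (`--r2-margin`): the second
  upper bound only caps the force, and no canonical value exists, so a
  margin of one typical NOE-bin width is used.
- **Grouping.** All pairs from one deposited restraint — OR alternatives
  and pseudo-atom expansions — share one label (consecutive from 0 in
  file order), so the engine applies r⁻⁶ averaging across them.  Pair
  weights stay `fac = 1`; degeneracy is handled by the grouping, not by
  weighting.
- **Dihedrals.** The interval is traversed from the lower to the upper
  bound in the +360° direction; φ₀ is the arc midpoint, Δφ the half
  width.  A deposited target column, if any, is ignored — the midpoint
  definition keeps the flat bottom centred between the bounds.  Full
  circle intervals are rejected.  `kfac = 1` so the global `dihre-fc`
  controls stiffness.
- **Orientation restraints.** The observed coupling is copied in Hz;
  experiments are numbered per constraint-list save-frame and labels per
  experiment.  The dipolar constant comes from a small per-element-pair
  table (N–H 6.083 by default, configurable), exponent α = 3 — the
  standard dipolar settings; the restraint file format carries them
  explicitly so they can be overridden.
- **Chains.** NMR entity labels map to topology molecule blocks
  positionally (first entity ↔ first block), overridable with
  `--chain-map`; neither file names the other's chains, so any automatic
  rule is a convention and this one is the simplest to audit.  Residues
  are matched by author sequence number; residue-name mismatches (HIS vs
  the tautomer names) are logged and matching proceeds per atom, so only
  genuinely absent atoms (e.g. `HD1` on an ε-tautomer histidine) cause a
  restraint to be skipped — always with a warning, and the manifest
  asserts `parsed = emitted + skipped` per class.

## Validation analytics

Violations are instantaneous, per structure: distance violation
max(0, r_eff − r₁, r₀ − r_eff) on the r⁻⁶ effective distance (`mean`
convention by default; `sum` available for the ambiguous-NOE convention);
dihedral violation the angular excess outside the well; orientation
violation |D_calc − δ| after a per-experiment least-squares tensor fit on
the structure being scored (under five independent vectors the fit is
flagged underdetermined and the minimum-norm solution used).  In-run time
averaging (τ_dr) belongs to the MD engine; the converter only emits the
constant.

The distance RMSD uses all atom pairs of a subset — heavy atoms by
default, because hydrogen naming differs between schemes and hydrogens
carry no independent structural information here; `all` and `backbone`
are available.  The all-pairs cost is O(N²); a stride option exists for
very large chains and is off by default.

## The synthetic generator

`fixtures` builds peptides (11 residue types with Amber-named side
chains) with deterministic, chemically plausible but not energy-minimized
geometry: backbone atoms on a 0.38 nm Cα spacing, side chains grown along
fixed offsets, hydrogens on seeded random unit directions (which also
keeps N–H vectors non-collinear, so RDC fits are well determined).  Model
1 is the base geometry; further models add a 0.01 nm spread, emulating a
tight NMR ensemble.  Restraint bounds are *measured* on model 1 and
widened by 0.05 nm slack, so satisfaction is true by construction;
violated records pull the upper bound a prescribed magnitude below the
measured distance, and the generator records exactly which records it
violated.  RDC observations are forward-calculated from a fixed alignment
tensor on model-1 N–H vectors.

What the fixtures do **not** emulate: realistic NOE density or spin
diffusion, solvent, energetic strain, stereo-assignment ambiguity, or the
size of real depositions.  Tests passing on fixtures therefore establish
the conversion and evaluation logic (name translation, grouping, units,
labelling, circular averaging, tensor algebra), not force-field or
sampling behaviour on real proteins — those are covered by the separate
archive-download and minimization checks, which require network access
and the MD engine.

## Numerical notes

- Angles wrap into (−180°, 180°]; the flat-bottom dihedral energy is the
  continuous symmetric form ½k(|φ′|−Δφ)² with φ′ the wrapped deviation,
  which is periodic and continuous at the well edges.  (A literally
  transcribed textbook form subtracts φ₀ a second time inside the
  quadratic; the symmetric form is what a flat-bottom well means.)
- The linear tail of the distance potential meets the harmonic wall
  exactly at r₂: both branches evaluate to ½k(r₂−r₁)² there.
- Tensor fits use `numpy.linalg.lstsq` on the 5-parameter design
  c·(x²−z², y²−z², 2xy, 2xz, 2yz); symmetry and zero trace of the
  reconstructed matrix hold by construction.
- Conversion output is byte-deterministic for identical inputs and
  flags; logs are the only non-deterministic channel.

## Problem sizes

The test suite and acceptance script run on generated systems of 2–6
residues (≈ 30–90 atoms, 10–20 restraints per class), which exercises
every code path at sub-second cost; the conversion scales linearly in
restraint count and the distance RMSD quadratically in subset size.

## Known limitations

- NMR-STAR dialects: the standard 3.1 constraint loops plus simple
  two-atom distance loops are handled; NEF, peak lists and chemical-shift
  loops are out of scope.
- Stereo-specific assignment is not resolved; OR members are kept as
  deposited.
- Topology preprocessing follows the default `#ifdef` path only, and
  `#include` resolution is limited to the topology's directory.
- The positional chain-mapping convention can mispair entities in
  multi-chain systems with unusual ordering; use `--chain-map`.
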