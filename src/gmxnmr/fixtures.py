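"""Self-contained synthetic test inputs.

Builds toy peptides with chemically plausible (not energy-minimized)
geometry, a matching minimal GROMACS topology, and NMR-STAR restraint text
whose ground truth is known by construction: distance and dihedral bounds
are measured on model 1 and widened by a slack, except for a configurable
number of records that are deliberately violated by a prescribed
magnitude.  RDC loops are generated from a known alignment tensor, so the
tensor fit can be checked for exact recovery.

Everything is generated at run time from a seed — no downloads, no bundled
binaries — and the generator records exactly which restraints it violated
so pipeline reports can be compared against ground truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .potentials import dihedral_angle
from .structures import Ensemble, StructureModel

NM_TO_A = 10.0

#: side-chain atoms (Amber naming) as (atom, parent) chains; parent None = CA
SIDE_CHAINS: dict[str, list[tuple[str, Optional[str]]]] = {
    "GLY": [],
    "ALA": [("CB", None), ("HB1", "CB"), ("HB2", "CB"), ("HB3", "CB")],
    "SER": [("CB", None), ("HB1", "CB"), ("HB2", "CB"), ("OG", "CB"), ("HG", "OG")],
    "ILE": [("CB", None), ("HB", "CB"), ("CG2", "CB"), ("HG21", "CG2"),
            ("HG22", "CG2"), ("HG23", "CG2"), ("CG1", "CB"), ("HG11", "CG1"),
            ("HG12", "CG1"), ("CD", "CG1"), ("HD1", "CD"), ("HD2", "CD"),
            ("HD3", "CD")],
    "LEU": [("CB", None), ("HB1", "CB"), ("HB2", "CB"), ("CG", "CB"), ("HG", "CG"),
            ("CD1", "CG"), ("HD11", "CD1"), ("HD12", "CD1"), ("HD13", "CD1"),
            ("CD2", "CG"), ("HD21", "CD2"), ("HD22", "CD2"), ("HD23", "CD2")],
    "LYS": [("CB", None), ("HB1", "CB"), ("HB2", "CB"), ("CG", "CB"), ("HG1", "CG"),
            ("HG2", "CG"), ("CD", "CG"), ("HD1", "CD"), ("HD2", "CD"),
            ("CE", "CD"), ("HE1", "CE"), ("HE2", "CE"), ("NZ", "CE"),
            ("HZ1", "NZ"), ("HZ2", "NZ"), ("HZ3", "NZ")],
    "MET": [("CB", None), ("HB1", "CB"), ("HB2", "CB"), ("CG", "CB"), ("HG1", "CG"),
            ("HG2", "CG"), ("SD", "CG"), ("CE", "SD"), ("HE1", "CE"),
            ("HE2", "CE"), ("HE3", "CE")],
    "PHE": [("CB", None), ("HB1", "CB"), ("HB2", "CB"), ("CG", "CB"),
            ("CD1", "CG"), ("HD1", "CD1"), ("CD2", "CG"), ("HD2", "CD2"),
            ("CE1", "CD1"), ("HE1", "CE1"), ("CE2", "CD2"), ("HE2", "CE2"),
            ("CZ", "CE1"), ("HZ", "CZ")],
    "TYR": [("CB", None), ("HB1", "CB"), ("HB2", "CB"), ("CG", "CB"),
            ("CD1", "CG"), ("HD1", "CD1"), ("CD2", "CG"), ("HD2", "CD2"),
            ("CE1", "CD1"), ("HE1", "CE1"), ("CE2", "CD2"), ("HE2", "CE2"),
            ("CZ", "CE1"), ("OH", "CZ"), ("HH", "OH")],
    "ARG": [("CB", None), ("HB1", "CB"), ("HB2", "CB"), ("CG", "CB"), ("HG1", "CG"),
            ("HG2", "CG"), ("CD", "CG"), ("HD1", "CD"), ("HD2", "CD"),
            ("NE", "CD"), ("HE", "NE"), ("CZ", "NE"), ("NH1", "CZ"),
            ("HH11", "NH1"), ("HH12", "NH1"), ("NH2", "CZ"),
            ("HH21", "NH2"), ("HH22", "NH2")],
    # epsilon-tautomer atoms (as Amber HIE): deliberately no HD1 proton
    "HIS": [("CB", None), ("HB1", "CB"), ("HB2", "CB"), ("CG", "CB"),
            ("ND1", "CG"), ("CD2", "CG"), ("HD2", "CD2"), ("CE1", "ND1"),
            ("HE1", "CE1"), ("NE2", "CE1"), ("HE2", "NE2")],
}

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

_HEAVY_DIRS = np.array([
    (0.00, -0.150, 0.000), (0.100, -0.110, 0.060), (-0.100, -0.110, -0.060),
    (0.020, -0.120, 0.120), (0.120, -0.040, -0.100),
])


@dataclass
class FixtureSpec:
    """Parameters of one synthetic test system.

    ``violation_magnitude`` [nm] is the constructed excess over the first
    upper bound for deliberately violated distance records;
    ``dihedral_violation`` [degrees] likewise for torsions.
    """

    sequence: tuple[str, ...] = ("ALA", "GLY", "ILE", "LEU", "SER", "LYS")
    n_models: int = 5
    seed: int = 2021
    n_satisfied: int = 10
    n_violated: int = 0
    violation_magnitude: float = 0.05
    n_dihedrals: int = 0
    n_violated_dihedrals: int = 0
    dihedral_violation: float = 10.0
    n_rdc: int = 0
    slack: float = 0.05           # nm widening of satisfied bounds
    model_spread: float = 0.01    # nm ensemble spread around model 1
    chain_label: str = "1"

    def __post_init__(self) -> None:
        self.sequence = tuple(r.upper() for r in self.sequence)
        if len(self.sequence) < 2:
            raise ValueError("need at least two residues")
        unknown = [r for r in self.sequence if r not in SIDE_CHAINS]
        if unknown:
            raise ValueError(f"unsupported residues: {unknown}")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


@dataclass
class GroundTruth:
    """What the generator built, for comparison with pipeline reports."""

    n_distance: int = 0
    violated_distance: dict[int, float] = field(default_factory=dict)
    n_dihedral: int = 0
    violated_dihedral: dict[int, float] = field(default_factory=dict)
    n_rdc: int = 0
    rdc_tensor: Optional[list[list[float]]] = None

    def to_dict(self) -> dict:
        return asdict(self)


def _element(name: str) -> str:
    return "H" if name.lstrip("0123456789").upper().startswith("H") else name[0].upper()


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_peptide(spec: FixtureSpec) -> tuple[Ensemble, str]:
    """Idealized peptide ensemble plus a matching minimal topology.

    Model 1 is the base geometry; models 2..n add a small seeded
    displacement (``model_spread``).  The topology ``[ atoms ]`` section
    lists exactly the ensemble's atoms, in the same order.
    """
    rng = np.random.default_rng(spec.seed)
    coords: dict[int, np.ndarray] = {}
    atom_names: dict[int, str] = {}
    residue_names: dict[int, str] = {}
    residue_seqs: dict[int, int] = {}
    idx = 0

    for rnum, res in enumerate(spec.sequence, start=1):
        origin = np.array([0.38 * (rnum - 1), 0.03 * (rnum % 2), 0.0])
        placed: dict[str, np.ndarray] = {}

        def put(name: str, pos: np.ndarray) -> None:
            nonlocal idx
            idx += 1
            jitter = rng.uniform(-0.005, 0.005, size=3)
            coords[idx] = pos + jitter
            placed[name] = coords[idx]
            atom_names[idx] = name
            residue_names[idx] = res
            residue_seqs[idx] = rnum

        put("N", origin + (-0.145, 0.095, 0.0))
        put("H", placed["N"] + 0.100 * _unit(rng))
        put("CA", origin)
        if res == "GLY":
            put("HA1", placed["CA"] + 0.109 * _unit(rng))
            put("HA2", placed["CA"] + 0.109 * _unit(rng))
        else:
            put("HA", placed["CA"] + 0.109 * _unit(rng))
        heavy_count: dict[str, int] = {}
        for name, parent in SIDE_CHAINS[res]:
            base = placed[parent] if parent else placed["CA"]
            if _element(name) == "H":
                put(name, base + 0.105 * _unit(rng))
            else:
                k = heavy_count.get(parent or "CA", 0)
                heavy_count[parent or "CA"] = k + 1
                put(name, base + _HEAVY_DIRS[k % len(_HEAVY_DIRS)])
        put("C", origin + (0.145, 0.085, 0.0))
        put("O", placed["C"] + 0.123 * _unit(rng))

    base_model = StructureModel(model_id=1, coordinates=coords)
    models = [base_model]
    for m in range(2, spec.n_models + 1):
        noise = {i: xyz + rng.normal(0.0, spec.model_spread / math.sqrt(3), size=3)
                 for i, xyz in coords.items()}
        models.append(StructureModel(model_id=m, coordinates=noise))
    ensemble = Ensemble(models=models, atom_names=atom_names,
                        residue_names=residue_names, residue_seqs=residue_seqs)

    top = ["[ moleculetype ]", "; name  nrexcl", "Peptide   3", "",
           "[ atoms ]", ";  nr  type  resnr  residue  atom  cgnr  charge  mass"]
    for i in sorted(coords):
        el = _element(atom_names[i])
        top.append(f"{i:5d}  {el:<4s}{residue_seqs[i]:5d}  {residue_names[i]:<6s}"
                   f"{atom_names[i]:<6s}{i:5d}  {0.0:7.3f}  {_MASSES[el]:7.3f}")
    top += ["", "[ system ]", "Synthetic peptide fixture", "",
            "[ molecules ]", "Peptide   1", ""]
    return ensemble, "\n".join(top)


# ---------------------------------------------------------------------------
# NMR-STAR generation
# ---------------------------------------------------------------------------

def _find(ensemble: Ensemble, resseq: int, name: str) -> int:
    for i in ensemble.models[0].indices:
        if ensemble.residue_seqs[i] == resseq and ensemble.atom_names[i] == name:
            return i
    raise KeyError(f"{name} of residue {resseq} not in fixture")


def _dist(ensemble: Ensemble, i: int, j: int) -> float:
    m = ensemble.models[0]
    return float(np.linalg.norm(m[j] - m[i]))


def make_star(spec: FixtureSpec, ensemble: Ensemble) -> tuple[str, GroundTruth]:
    """NMR-STAR text with known record counts, bounds, and violations.

    Distance records pair backbone amide protons of different residues;
    bounds are measured on model 1 and widened by ``slack``, except the
    last ``n_violated`` records whose upper bound is pulled
    ``violation_magnitude`` nm below the measured distance.  Optional
    torsion (PHI) and RDC (N-H) loops follow the same construction.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_res = spec.n_residues
    truth = GroundTruth()
    chain = spec.chain_label

    dist_rows = []
    n_total = spec.n_satisfied + spec.n_violated
    pairs = [(a, b) for a in range(1, n_res + 1) for b in range(a + 1, n_res + 1)]
    if n_total > len(pairs):
        raise ValueError("more distance records requested than residue pairs")
    chosen = [pairs[k] for k in rng.choice(len(pairs), size=n_total, replace=False)]
    for rid, (ra, rb) in enumerate(chosen, start=1):
        d = _dist(ensemble, _find(ensemble, ra, "H"), _find(ensemble, rb, "H"))
        violated = rid > spec.n_satisfied
        if violated:
            upper = d - spec.violation_magnitude
            lower = 0.0
            truth.violated_distance[rid] = spec.violation_magnitude
        else:
            upper = d + spec.slack
            lower = max(0.0, d - spec.slack)
        dist_rows.append(
            f"    {rid:4d} . {chain} {ra} {ra} "
            f"{spec.sequence[ra-1]} H {chain} {rb} {rb} {spec.sequence[rb-1]} H "
            f"{lower * NM_TO_A:.6f} {upper * NM_TO_A:.6f}")
    truth.n_distance = n_total

    dih_rows = []
    n_dih = spec.n_dihedrals + spec.n_violated_dihedrals
    if n_dih > n_res - 1:
        raise ValueError("more PHI restraints requested than interior residues")
    m1 = ensemble.models[0]
    for k in range(n_dih):
        rnum = k + 2  # PHI defined from residue 2 on
        rid = k + 1
        atoms = [(rnum - 1, "C"), (rnum, "N"), (rnum, "CA"), (rnum, "C")]
        phi = dihedral_angle(*[m1[_find(ensemble, rs, nm)] for rs, nm in atoms])
        if k < spec.n_dihedrals:
            lower, upper = phi - 20.0, phi + 20.0
        else:
            centre = phi - (10.0 + spec.dihedral_violation)
            lower, upper = centre - 10.0, centre + 10.0
            truth.violated_dihedral[rid] = spec.dihedral_violation
        parts = [f"    {rid:4d} PHI"]
        for rs, nm in atoms:
            parts.append(f"{chain} {rs} {rs} {spec.sequence[rs-1]} {nm}")
        parts.append(f"{lower:.6f} {upper:.6f}")
        dih_rows.append(" ".join(parts))
    truth.n_dihedral = n_dih

    rdc_rows = []
    if spec.n_rdc:
        if spec.n_rdc > n_res:
            raise ValueError("more RDC records requested than residues")
        tensor = np.array([[1.0, 0.3, -0.2],
                           [0.3, -0.6, 0.4],
                           [-0.2, 0.4, -0.4]])
        truth.rdc_tensor = tensor.tolist()
        const = 6.083
        for k in range(spec.n_rdc):
            rnum = k + 1
            i, j = _find(ensemble, rnum, "N"), _find(ensemble, rnum, "H")
            v = m1[j] - m1[i]
            v = v / np.linalg.norm(v)
            obs = const * float(v @ tensor @ v)
            rdc_rows.append(
                f"    {k + 1:4d} {chain} {rnum} {rnum} {spec.sequence[rnum-1]} N "
                f"{chain} {rnum} {rnum} {spec.sequence[rnum-1]} H {obs:.8f} 0.0")
        truth.n_rdc = spec.n_rdc

    blocks = ["data_synthetic_fixture", ""]
    if dist_rows:
        blocks += [
            "save_distance_constraints_1",
            "   _Gen_dist_constraint_list.Sf_category   general_distance_constraints",
            "   _Gen_dist_constraint_list.ID             1",
            "   loop_",
            "      _Gen_dist_constraint.ID",
            "      _Gen_dist_constraint.Member_logic_code",
            "      _Gen_dist_constraint.Entity_assembly_ID_1",
            "      _Gen_dist_constraint.Comp_index_ID_1",
            "      _Gen_dist_constraint.Auth_seq_ID_1",
            "      _Gen_dist_constraint.Comp_ID_1",
            "      _Gen_dist_constraint.Atom_ID_1",
            "      _Gen_dist_constraint.Entity_assembly_ID_2",
            "      _Gen_dist_constraint.Comp_index_ID_2",
            "      _Gen_dist_constraint.Auth_seq_ID_2",
            "      _Gen_dist_constraint.Comp_ID_2",
            "      _Gen_dist_constraint.Atom_ID_2",
            "      _Gen_dist_constraint.Distance_lower_bound_val",
            "      _Gen_dist_constraint.Distance_upper_bound_val",
            *dist_rows,
            "   stop_",
            "save_", ""]
    if dih_rows:
        blocks += [
            "save_torsion_angle_constraints_1",
            "   _Torsion_angle_constraint_list.Sf_category   torsion_angle_constraints",
            "   _Torsion_angle_constraint_list.ID             1",
            "   loop_",
            "      _Torsion_angle_constraint.ID",
            "      _Torsion_angle_constraint.Torsion_angle_name",
            *[f"      _Torsion_angle_constraint.{tag}_{k}"
              for k in range(1, 5)
              for tag in ("Entity_assembly_ID", "Comp_index_ID", "Auth_seq_ID",
                          "Comp_ID", "Atom_ID")],
            "      _Torsion_angle_constraint.Angle_lower_bound_val",
            "      _Torsion_angle_constraint.Angle_upper_bound_val",
            *dih_rows,
            "   stop_",
            "save_", ""]
    if rdc_rows:
        blocks += [
            "save_RDC_constraints_1",
            "   _RDC_constraint_list.Sf_category   RDC_constraints",
            "   _RDC_constraint_list.ID             1",
            "   loop_",
            "      _RDC_constraint.ID",
            "      _RDC_constraint.Entity_assembly_ID_1",
            "      _RDC_constraint.Comp_index_ID_1",
            "      _RDC_constraint.Auth_seq_ID_1",
            "      _RDC_constraint.Comp_ID_1",
            "      _RDC_constraint.Atom_ID_1",
            "      _RDC_constraint.Entity_assembly_ID_2",
            "      _RDC_constraint.Comp_index_ID_2",
            "      _RDC_constraint.Auth_seq_ID_2",
            "      _RDC_constraint.Comp_ID_2",
            "      _RDC_constraint.Atom_ID_2",
            "      _RDC_constraint.RDC_val",
            "      _RDC_constraint.RDC_val_err",
            *rdc_rows,
            "   stop_",
            "save_", ""]
    return "\n".join(blocks), truth


def perturb(model: StructureModel, magnitude: float, seed: int) -> StructureModel:
    """Copy of a model with zero-mean displacement of RMS ~ magnitude [nm]."""
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return StructureModel(model_id=model.model_id,
                              coordinates=dict(model.coordinates))
    rng = np.random.default_rng(seed)
    sigma = magnitude / math.sqrt(3.0)
    coords = {i: xyz + rng.normal(0.0, sigma, size=3)
              for i, xyz in model.coordinates.items()}
    return StructureModel(model_id=model.model_id, coordinates=coords)
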