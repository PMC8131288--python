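"""Typed records for restraints as they appear in an NMR deposition.

These are the *raw* records: atom addresses still use NMR identifiers
(pseudo-atoms such as MB or QD included), distances are in Angstrom and
angles in degrees, exactly as deposited.  Force-field naming, unit
conversion and topology indexing happen downstream.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

#: 3-letter amino acid codes plus the nucleotide codes used in NMR-STAR.
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL".split()
)
NUCLEOTIDES = frozenset("G A U C DG DA DT DC".split())
KNOWN_RESIDUES = AMINO_ACIDS | NUCLEOTIDES


@dataclass(frozen=True)
class AtomSpec:
    """Address of one atom (or pseudo-atom) in NMR terms.

    ``atom_id`` is the identifier as deposited and may denote a degenerate
    group (MB, QD, H5'' ...); ``residue_seq`` is the author sequence number.
    """

    chain_label: str
    residue_seq: int
    residue_name: str
    atom_id: str

    def __post_init__(self) -> None:
        if self.residue_seq < 1:
            raise ValueError(f"residue_seq must be >= 1, got {self.residue_seq}")
        if not self.atom_id:
            raise ValueError("atom_id must be non-empty")

    @property
    def residue_known(self) -> bool:
        return self.residue_name.upper() in KNOWN_RESIDUES


@dataclass
class RawDistanceRecord:
    """One distance restraint; ``members`` are logical-OR alternatives."""

    restraint_id: int
    members: list[tuple[AtomSpec, AtomSpec]]
    lower_bound: float  # Angstrom
    upper_bound: float  # Angstrom
    target: Optional[float] = None  # Angstrom

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("distance record needs at least one member pair")
        if not (0.0 <= self.lower_bound <= self.upper_bound):
            raise ValueError(
                f"bounds must satisfy 0 <= lower <= upper, got "
                f"({self.lower_bound}, {self.upper_bound})"
            )


@dataclass
class RawDihedralRecord:
    """One torsion-angle restraint: four ordered atoms and an angle interval."""

    restraint_id: int
    atoms: tuple[AtomSpec, AtomSpec, AtomSpec, AtomSpec]
    angle_lower: float  # degrees
    angle_upper: float  # degrees
    angle_name: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if len(self.atoms) != 4:
            raise ValueError("dihedral record needs exactly four atoms")
        if len(set(self.atoms)) != 4:
            raise ValueError("dihedral atoms must be distinct")


@dataclass
class RawOrientationRecord:
    """One residual-dipolar-coupling restraint (observed coupling in Hz)."""

    restraint_id: int
    atoms: tuple[AtomSpec, AtomSpec]
    observed: float  # Hz
    error: Optional[float] = None  # Hz
    experiment_id: int = 1

    def __post_init__(self) -> None:
        if self.atoms[0] == self.atoms[1]:
            raise ValueError("orientation restraint atoms must be distinct")
        if self.experiment_id < 1:
            raise ValueError("experiment_id must be >= 1")


@dataclass
class RestraintSets:
    """All restraints extracted from one deposition."""

    distances: list[RawDistanceRecord] = field(default_factory=list)
    dihedrals: list[RawDihedralRecord] = field(default_factory=list)
    orientations: list[RawOrientationRecord] = field(default_factory=list)
    source_label: str = ""
    #: human-readable messages for rows that could not be kept
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("distances", "dihedrals", "orientations"):
            ids = [r.restraint_id for r in getattr(self, name)]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate restraint ids in {name}")

    # -- debug serialization (round-trips exactly) -------------------------
    def to_json(self) -> str:
        def atom(a: AtomSpec) -> dict:
            return asdict(a)

        payload = {
            "source_label": self.source_label,
            "warnings": list(self.warnings),
            "distances": [
                {
                    "restraint_id": r.restraint_id,
                    "members": [[atom(a), atom(b)] for a, b in r.members],
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "target": r.target,
                }
                for r in self.distances
            ],
            "dihedrals": [
                {
                    "restraint_id": r.restraint_id,
                    "atoms": [atom(a) for a in r.atoms],
                    "angle_lower": r.angle_lower,
                    "angle_upper": r.angle_upper,
                    "angle_name": r.angle_name,
                }
                for r in self.dihedrals
            ],
            "orientations": [
                {
                    "restraint_id": r.restraint_id,
                    "atoms": [atom(a) for a in r.atoms],
                    "observed": r.observed,
                    "error": r.error,
                    "experiment_id": r.experiment_id,
                }
                for r in self.orientations
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RestraintSets":
        payload = json.loads(text)

        def atom(d: dict) -> AtomSpec:
            return AtomSpec(**d)

        return cls(
            distances=[
                RawDistanceRecord(
                    restraint_id=d["restraint_id"],
                    members=[(atom(a), atom(b)) for a, b in d["members"]],
                    lower_bound=d["lower_bound"],
                    upper_bound=d["upper_bound"],
                    target=d["target"],
                )
                for d in payload["distances"]
            ],
            dihedrals=[
                RawDihedralRecord(
                    restraint_id=d["restraint_id"],
                    atoms=tuple(atom(a) for a in d["atoms"]),
                    angle_lower=d["angle_lower"],
                    angle_upper=d["angle_upper"],
                    angle_name=d["angle_name"],
                )
                for d in payload["dihedrals"]
            ],
            orientations=[
                RawOrientationRecord(
                    restraint_id=d["restraint_id"],
                    atoms=tuple(atom(a) for a in d["atoms"]),
                    observed=d["observed"],
                    error=d["error"],
                    experiment_id=d["experiment_id"],
                )
                for d in payload["orientations"]
            ],
            source_label=payload["source_label"],
            warnings=list(payload["warnings"]),
        )
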