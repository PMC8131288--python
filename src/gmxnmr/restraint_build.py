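"""Turn raw NMR records into GROMACS-ready restraints and write them out.

Distance restraints become flat-bottom potentials

    V(r) = 0                      for r0 <= r < r1
         = k_dr/2 (r - r0)^2      for r < r0
         = k_dr/2 (r - r1)^2      for r1 <= r < r2
         = k_dr/2 (r2 - r1)(2r - r2 - r1)   for r >= r2  (linear tail)

with r0/r1 taken from the deposited bounds (Angstrom -> nm) and r2 a
configurable margin above r1 to cap the force.  All atom pairs arising from
one deposited restraint — logical-OR alternatives and pseudo-atom
expansions alike — share a single restraint label, which makes GROMACS
treat them as one restraint under r^-6 averaging.

Dihedral intervals are reduced to a centre and half-width on the circle;
the midpoint is taken along the arc from the lower to the upper bound in
the increasing (mod 360 deg) direction, so intervals that straddle the
+/-180 deg seam average correctly.

Orientation (RDC) restraints are copied through with the observed coupling
in Hz, numbered per alignment experiment.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from .nomenclature import Translator, default_translator, DihedralTranslationError
from .records import (
    RawDihedralRecord,
    RawDistanceRecord,
    RawOrientationRecord,
    RestraintSets,
)
from .topology_map import Miss, TopologyIndex, chain_positions

logger = logging.getLogger(__name__)

A_TO_NM = 0.1


@dataclass
class ConverterConfig:
    """Conversion parameters; force constants match the recommended run setup.

    k_dr [kJ mol-1 nm-2] and tau_dr [ps] are the distance-restraint force
    constant and time-averaging constant (recommended 1000 and 500);
    k_dihr [kJ mol-1 rad-2] and k_or [kJ mol-1 Hz-2] the dihedral and
    orientation force constants (1000 and 10).  r2_margin [nm] sets the
    second upper bound r2 = r1 + margin that caps restraint forces.
    """

    force_field: str = "amber"
    k_dr: float = 1000.0
    tau_dr: float = 500.0
    k_dihr: float = 1000.0
    k_or: float = 10.0
    r2_margin: float = 0.1
    averaging: str = "mean"  # r^-6 averaging convention: mean | sum

    def __post_init__(self) -> None:
        if self.force_field not in ("amber", "charmm"):
            raise ValueError(f"unsupported force field {self.force_field!r}")
        if self.averaging not in ("mean", "sum"):
            raise ValueError(f"averaging must be 'mean' or 'sum', not {self.averaging!r}")
        for name in ("k_dr", "tau_dr", "k_dihr", "k_or", "r2_margin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DistanceRestraint:
    label: int
    pairs: list[tuple[int, int]]
    r0: float  # nm
    r1: float  # nm
    r2: float  # nm
    fac: float = 1.0
    source_id: int | None = None  # deposited restraint id, if any

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("distance restraint needs at least one pair")
        if not (0.0 <= self.r0 <= self.r1 <= self.r2):
            raise ValueError(f"need 0 <= r0 <= r1 <= r2, got "
                             f"({self.r0}, {self.r1}, {self.r2})")
        if self.fac <= 0:
            raise ValueError("fac must be > 0")


@dataclass
class DihedralRestraint:
    atoms: tuple[int, int, int, int]
    phi0: float  # degrees, in (-180, 180]
    dphi: float  # degrees, >= 0
    kfac: float = 1.0
    source_id: int | None = None

    def __post_init__(self) -> None:
        if self.dphi < 0:
            raise ValueError("dphi must be >= 0")
        if not (-180.0 < self.phi0 <= 180.0):
            raise ValueError("phi0 must lie in (-180, 180]")


@dataclass
class OrientationRestraint:
    atoms: tuple[int, int]
    experiment: int
    label: int
    obs: float  # Hz
    alpha: float = 3.0
    const: float = 6.083  # dipolar constant, N-H default
    weight: float = 1.0  # Hz^-2
    source_id: int | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


#: dipolar constants per unordered element pair; N-H is the common RDC probe.
DIPOLAR_CONSTANTS = {
    frozenset({"N", "H"}): 6.083,
    frozenset({"C", "H"}): 15.31,
    frozenset({"C", "N"}): 1.54,
}


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = math.fmod(angle, 360.0)
    if wrapped <= -180.0:
        wrapped += 360.0
    elif wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _resolve_spec(spec, index: TopologyIndex, chain_map: dict[str, int]):
    pos = chain_map.get(spec.chain_label, 0)
    return index.resolve(pos, spec.residue_seq, spec.atom_id,
                         residue_name=spec.residue_name)


def build_distance(record: RawDistanceRecord, label: int, index: TopologyIndex,
                   config: ConverterConfig,
                   translator: Optional[Translator] = None,
                   chain_map: Optional[dict[str, int]] = None
                   ) -> DistanceRestraint | Miss:
    """Expand one raw distance record into a labelled GROMACS restraint.

    Returns a :class:`Miss` (restraint skipped) if any atom of any OR
    member fails to resolve in the topology.
    """
    translator = translator or default_translator()
    chain_map = chain_map if chain_map is not None else {}
    pairs: list[tuple[int, int]] = []
    for a, b in record.members:
        for ea, eb in translator.expand_pair(a, b, config.force_field):
            ia = _resolve_spec(ea.spec, index, chain_map)
            ib = _resolve_spec(eb.spec, index, chain_map)
            for atom, res in ((ea, ia), (eb, ib)):
                if isinstance(res, Miss):
                    return Miss(f"distance restraint {record.restraint_id}: "
                                f"{res.reason} (from identifier {atom.origin})")
            pairs.append((ia, ib))
    r0 = record.lower_bound * A_TO_NM
    r1 = record.upper_bound * A_TO_NM
    return DistanceRestraint(label=label, pairs=pairs, r0=r0, r1=r1,
                             r2=r1 + config.r2_margin, fac=1.0,
                             source_id=record.restraint_id)


def circular_interval(angle_lower: float, angle_upper: float) -> tuple[float, float]:
    """Centre and half-width of the arc from lower to upper (increasing).

    The arc is traversed from the lower to the upper bound in the +360 deg
    direction, so (170, -170) denotes the 20 deg arc through 180 deg.
    Degenerate intervals (lower == upper) have zero width; a full-circle
    arc is rejected as meaningless.
    """
    width = math.fmod(angle_upper - angle_lower, 360.0)
    if width < 0:
        width += 360.0
    if angle_upper != angle_lower and width == 0.0:
        raise ValueError("dihedral interval spans the full circle")
    phi0 = wrap_angle(angle_lower + width / 2.0)
    return phi0, width / 2.0


def build_dihedral(record: RawDihedralRecord, index: TopologyIndex,
                   config: ConverterConfig,
                   translator: Optional[Translator] = None,
                   chain_map: Optional[dict[str, int]] = None
                   ) -> DihedralRestraint | Miss:
    """Translate, resolve and circularly average one torsion restraint."""
    translator = translator or default_translator()
    chain_map = chain_map if chain_map is not None else {}
    names = translator.translate_dihedral(record, config.force_field)
    indices = []
    for atom, name in zip(record.atoms, names):
        res = index.resolve(chain_map.get(atom.chain_label, 0), atom.residue_seq,
                            name, residue_name=atom.residue_name)
        if isinstance(res, Miss):
            return Miss(f"dihedral restraint {record.restraint_id}: {res.reason}")
        indices.append(res)
    phi0, dphi = circular_interval(record.angle_lower, record.angle_upper)
    return DihedralRestraint(atoms=tuple(indices), phi0=phi0, dphi=dphi, kfac=1.0,
                             source_id=record.restraint_id)


def build_orientation(record: RawOrientationRecord, label: int,
                      index: TopologyIndex, config: ConverterConfig,
                      translator: Optional[Translator] = None,
                      chain_map: Optional[dict[str, int]] = None
                      ) -> OrientationRestraint | Miss:
    """Resolve one RDC record; the observed coupling is copied through in Hz."""
    translator = translator or default_translator()
    chain_map = chain_map if chain_map is not None else {}
    indices = []
    elements = []
    for atom in record.atoms:
        names = translator.translate_atom(atom.residue_name, atom.atom_id,
                                          config.force_field)
        if len(names) != 1:
            return Miss(f"orientation restraint {record.restraint_id}: identifier "
                        f"{atom.atom_id} denotes {len(names)} atoms")
        res = index.resolve(chain_map.get(atom.chain_label, 0), atom.residue_seq,
                            names[0], residue_name=atom.residue_name)
        if isinstance(res, Miss):
            return Miss(f"orientation restraint {record.restraint_id}: {res.reason}")
        indices.append(res)
        elements.append(_element_of(names[0]))
    const = DIPOLAR_CONSTANTS.get(frozenset(elements), 6.083)
    weight = 1.0 if record.error in (None, 0.0) else 1.0 / record.error ** 2
    return OrientationRestraint(atoms=tuple(indices), experiment=record.experiment_id,
                                label=label, obs=record.observed, const=const,
                                weight=weight, source_id=record.restraint_id)


# ---------------------------------------------------------------------------
# whole-deposition conversion
# ---------------------------------------------------------------------------

@dataclass
class ConversionResult:
    distances: list[DistanceRestraint] = field(default_factory=list)
    dihedrals: list[DihedralRestraint] = field(default_factory=list)
    orientations: list[OrientationRestraint] = field(default_factory=list)
    skipped: dict[str, int] = field(default_factory=lambda: {
        "distance": 0, "dihedral": 0, "orientation": 0})
    warnings: list[str] = field(default_factory=list)


def convert(sets: RestraintSets, index: TopologyIndex, config: ConverterConfig,
            translator: Optional[Translator] = None,
            chain_override: Optional[dict[str, int]] = None) -> ConversionResult:
    """Convert a whole deposition; unresolvable restraints are skipped with
    a warning, and emitted restraints are labelled consecutively from 0."""
    translator = translator or default_translator()
    labels_seen = [s.chain_label for rec in sets.distances for a, b in rec.members
                   for s in (a, b)]
    labels_seen += [a.chain_label for rec in sets.dihedrals for a in rec.atoms]
    labels_seen += [a.chain_label for rec in sets.orientations for a in rec.atoms]
    chain_map = chain_positions(labels_seen, override=chain_override)

    out = ConversionResult()
    label = 0
    for rec in sets.distances:
        built = build_distance(rec, label, index, config, translator, chain_map)
        if isinstance(built, Miss):
            out.skipped["distance"] += 1
            out.warnings.append(built.reason)
            logger.warning("%s; restraint skipped", built.reason)
            continue
        out.distances.append(built)
        label += 1
    for rec in sets.dihedrals:
        try:
            built = build_dihedral(rec, index, config, translator, chain_map)
        except DihedralTranslationError as exc:
            built = Miss(str(exc))
        if isinstance(built, Miss):
            out.skipped["dihedral"] += 1
            out.warnings.append(built.reason)
            logger.warning("%s; restraint skipped", built.reason)
            continue
        out.dihedrals.append(built)
    or_label: dict[int, int] = {}
    for rec in sets.orientations:
        next_label = or_label.get(rec.experiment_id, 0) + 1
        built = build_orientation(rec, next_label, index, config, translator, chain_map)
        if isinstance(built, Miss):
            out.skipped["orientation"] += 1
            out.warnings.append(built.reason)
            logger.warning("%s; restraint skipped", built.reason)
            continue
        or_label[rec.experiment_id] = next_label
        out.orientations.append(built)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_itp(restraints, kind: str, source: str = "", force_field: str = "") -> str:
    """Serialize restraints to a GROMACS ``.itp`` include section.

    ``kind`` is one of ``distance``, ``dihedral``, ``orientation``.
    Output is deterministic and fixed-width.
    """
    header = f"; {kind} restraints"
    if source:
        header += f" generated from {source}"
    if force_field:
        header += f" (force field: {force_field})"
    lines = [header]
    if kind == "distance":
        lines.append("[ distance_restraints ]")
        lines.append(";   ai    aj  type label type'      low      up1      up2      fac")
        for r in restraints:
            for ai, aj in r.pairs:
                lines.append(f"{ai:6d}{aj:6d}{1:6d}{r.label:6d}{1:6d}"
                             f"{r.r0:9.4f}{r.r1:9.4f}{r.r2:9.4f}{r.fac:9.3f}")
    elif kind == "dihedral":
        lines.append("[ dihedral_restraints ]")
        lines.append(";   ai    aj    ak    al  type     phi0     dphi     kfac")
        for r in restraints:
            ai, aj, ak, al = r.atoms
            lines.append(f"{ai:6d}{aj:6d}{ak:6d}{al:6d}{1:6d}"
                         f"{r.phi0:9.3f}{r.dphi:9.3f}{r.kfac:9.3f}")
    elif kind == "orientation":
        lines.append("[ orientation_restraints ]")
        lines.append(";   ai    aj  type   exp label alpha    const      obs   weight")
        for r in restraints:
            ai, aj = r.atoms
            lines.append(f"{ai:6d}{aj:6d}{1:6d}{r.experiment:6d}{r.label:6d}"
                         f"{r.alpha:6.0f}{r.const:9.3f}{r.obs:9.3f}{r.weight:9.3f}")
    else:
        raise ValueError(f"unknown restraint kind {kind!r}")
    return "\n".join(lines) + "\n"


def write_mdp_fragment(config: ConverterConfig) -> str:
    """Run-parameter fragment enabling time-averaged restraints."""
    return "\n".join([
        "; restraint run parameters",
        "disre                    = simple",
        "disre-weighting          = conservative",
        f"disre-fc                 = {config.k_dr:g}",
        f"disre-tau                = {config.tau_dr:g}",
        "nstdisreout              = 0",
        f"dihre-fc                 = {config.k_dihr:g}",
        "orire                    = yes",
        f"orire-fc                 = {config.k_or:g}",
        "orire-tau                = 0",
        "orire-fitgrp             = backbone",
    ]) + "\n"
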