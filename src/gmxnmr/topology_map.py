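"""Index a GROMACS topology so restraint atoms can be numbered.

GROMACS restraint files refer to atoms by their global 1-based position in
the system.  This module reads the ``[ atoms ]`` sections of a topology
(``.top``/``.itp``; ``#include``s resolved relative to the file), lays the
molecules out in ``[ molecules ]`` order, and offers a
``(chain, residue number, atom name)`` lookup.

Lookup misses are values, not exceptions: the converter's contract is to
*skip* a restraint it cannot place (e.g. an HD1 proton on a histidine that
the force field modeled as the epsilon tautomer) and warn, never to die.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

logger = logging.getLogger(__name__)


class TopologyError(ValueError):
    pass


@dataclass
class Miss:
    """Why an atom could not be resolved."""

    reason: str

    def __bool__(self) -> bool:  # a miss is falsy; an index is truthy
        return False


@dataclass
class MoleculeType:
    name: str
    # per-atom (resnr, residue_name, atom_name) in file order
    atoms: list[tuple[int, str, str]] = field(default_factory=list)


@dataclass
class TopologyIndex:
    """Global 1-based atom numbering across all chains of the system."""

    #: (chain position, residue number, atom name) -> global index
    lookup: dict[tuple[int, int, str], int]
    #: (chain position, residue number) -> residue name
    residue_names: dict[tuple[int, int], str]
    #: moleculetype name per chain position
    chain_order: list[str]
    n_atoms: int

    def resolve(self, chain_pos: int, residue_seq: int, atom_name: str,
                residue_name: Optional[str] = None) -> int | Miss:
        """Global index for an atom, or a :class:`Miss` with the reason."""
        key = (chain_pos, residue_seq, atom_name.upper())
        hit = self.lookup.get(key)
        if hit is None:
            if (chain_pos, residue_seq) not in self.residue_names:
                return Miss(f"no residue {residue_seq} in chain {chain_pos}")
            top_res = self.residue_names[(chain_pos, residue_seq)]
            return Miss(
                f"atom {atom_name} not found at {top_res} {residue_seq} "
                f"(chain {chain_pos})"
            )
        if residue_name is not None:
            top_res = self.residue_names[(chain_pos, residue_seq)]
            if top_res.upper() != residue_name.upper():
                # HIS vs HISE/HID etc.: match positionally, note the difference
                logger.debug("residue name mismatch at %d: topology %s, restraint %s",
                             residue_seq, top_res, residue_name)
        return hit


_SECTION = re.compile(r"^\[\s*(\S+)\s*\]")
_INCLUDE = re.compile(r'^#include\s+"([^"]+)"')


def _strip(line: str) -> str:
    return line.split(";", 1)[0].strip()


def _read_lines(text: str, base_dir: Optional[Path]) -> list[str]:
    """Flatten #include directives (working-directory scope only)."""
    out: list[str] = []
    for raw in text.splitlines():
        m = _INCLUDE.match(raw.strip())
        if m:
            name = Path(m.group(1)).name  # no path escapes
            candidate = (base_dir or Path(".")) / name
            if candidate.exists():
                out.extend(_read_lines(candidate.read_text(), base_dir))
            else:
                logger.debug("include %s not found; ignored", m.group(1))
            continue
        if raw.lstrip().startswith("#"):  # other preprocessor lines: default path
            continue
        out.append(raw)
    return out


def read_topology(top_text: str, base_dir: str | Path | None = None) -> TopologyIndex:
    """Build a :class:`TopologyIndex` from GROMACS topology text.

    Raises
    ------
    TopologyError
        If no ``[ atoms ]`` section is found.
    """
    base = Path(base_dir) if base_dir else None
    lines = _read_lines(top_text, base)

    moltypes: dict[str, MoleculeType] = {}
    order_of_definition: list[str] = []
    system_molecules: list[tuple[str, int]] = []

    section = None
    current: Optional[MoleculeType] = None
    for raw in lines:
        line = _strip(raw)
        if not line:
            continue
        m = _SECTION.match(line)
        if m:
            section = m.group(1).lower()
            if section == "moleculetype":
                current = None
            continue
        if section == "moleculetype":
            name = line.split()[0]
            current = MoleculeType(name=name)
            moltypes[name] = current
            order_of_definition.append(name)
        elif section == "atoms":
            if current is None:  # an [ atoms ] block outside moleculetype
                current = MoleculeType(name="SYSTEM")
                moltypes[current.name] = current
                order_of_definition.append(current.name)
            cols = line.split()
            if len(cols) < 5:
                raise TopologyError(f"short [ atoms ] line: {line!r}")
            # nr type resnr residue atom ...
            current.atoms.append((int(cols[2]), cols[3], cols[4]))
        elif section == "molecules":
            cols = line.split()
            system_molecules.append((cols[0], int(cols[1])))

    if not any(mt.atoms for mt in moltypes.values()):
        raise TopologyError("topology contains no [ atoms ] section")

    if not system_molecules:
        system_molecules = [(name, 1) for name in order_of_definition
                            if moltypes[name].atoms]

    lookup: dict[tuple[int, int, str], int] = {}
    residue_names: dict[tuple[int, int], str] = {}
    chain_order: list[str] = []
    gidx = 0
    chain_pos = 0
    for name, count in system_molecules:
        if name not in moltypes:
            logger.debug("molecule %s has no [ atoms ] here (force-field species?); "
                         "skipped", name)
            continue
        mt = moltypes[name]
        if not mt.atoms:
            continue
        for _ in range(count):
            for resnr, resname, atomname in mt.atoms:
                gidx += 1
                key = (chain_pos, resnr, atomname.upper())
                if key in lookup:
                    raise TopologyError(f"duplicate atom {key} in topology")
                lookup[key] = gidx
                residue_names[(chain_pos, resnr)] = resname
            chain_order.append(name)
            chain_pos += 1
    return TopologyIndex(lookup=lookup, residue_names=residue_names,
                         chain_order=chain_order, n_atoms=gidx)


def read_topology_file(path: str | Path) -> TopologyIndex:
    path = Path(path)
    return read_topology(path.read_text(), base_dir=path.parent)


def chain_positions(chain_labels: list[str],
                    override: Optional[dict[str, int]] = None) -> dict[str, int]:
    """Positional mapping from NMR entity labels to topology chain slots.

    Neither file names the other's chains, so the first entity label seen
    maps to the first molecule block, and so on; ``override`` pins
    individual labels to explicit slots.
    """
    mapping: dict[str, int] = {}
    for label in chain_labels:
        if label not in mapping:
            mapping[label] = len(mapping)
    if override:
        mapping.update(override)
    return mapping
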