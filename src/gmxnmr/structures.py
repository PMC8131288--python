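"""In-memory coordinate models and ensemble file IO.

A :class:`StructureModel` maps global 1-based atom indices (the same
numbering a topology index produces) to coordinates in nm; an
:class:`Ensemble` is an ordered list of models over one common atom set,
as deposited in a multi-model PDB file.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

A_TO_NM = 0.1


@dataclass
class StructureModel:
    """One conformer: 1-based atom index -> (x, y, z) in nm."""

    model_id: int
    coordinates: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.coordinates = {int(i): np.asarray(xyz, dtype=float)
                            for i, xyz in self.coordinates.items()}
        for i, xyz in self.coordinates.items():
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite coordinates for atom {i}")

    def __getitem__(self, index: int) -> np.ndarray:
        return self.coordinates[index]

    def __contains__(self, index: int) -> bool:
        return index in self.coordinates

    @property
    def indices(self) -> list[int]:
        return sorted(self.coordinates)

    def array(self, subset: Optional[Iterable[int]] = None) -> np.ndarray:
        idx = sorted(subset) if subset is not None else self.indices
        return np.array([self.coordinates[i] for i in idx])


@dataclass
class Ensemble:
    """Ordered models over one shared atom set, with atom metadata."""

    models: list[StructureModel]
    atom_names: dict[int, str] = field(default_factory=dict)
    residue_names: dict[int, str] = field(default_factory=dict)
    residue_seqs: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("an ensemble needs at least one model")
        first = set(self.models[0].coordinates)
        for m in self.models[1:]:
            if set(m.coordinates) != first:
                raise ValueError("models of an ensemble must share one atom set")

    def __len__(self) -> int:
        return len(self.models)

    def subset(self, mode: str = "heavy") -> list[int]:
        """Atom indices for a comparison subset: heavy | all | backbone."""
        if mode == "all":
            return self.models[0].indices
        if mode == "heavy":
            return [i for i in self.models[0].indices
                    if not _is_hydrogen(self.atom_names.get(i, ""))]
        if mode == "backbone":
            return [i for i in self.models[0].indices
                    if self.atom_names.get(i, "").upper() in ("N", "CA", "C")]
        raise ValueError(f"unknown subset {mode!r}")


def _is_hydrogen(name: str) -> bool:
    stripped = name.strip().lstrip("0123456789")
    return stripped.upper().startswith("H")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb_models(source: str | Path) -> Ensemble:
    """Read a (multi-model) PDB file or text into an Ensemble (nm units).

    Atoms are numbered 1..N in order of appearance of the first model and
    matched across models by (chain, residue number, atom name).
    """
    import gemmi

    text = Path(source).read_text() if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ) else str(source)
    structure = gemmi.read_pdb_string(text)
    if len(structure) == 0:
        raise ValueError("PDB input contains no models")

    key_to_index: dict[tuple, int] = {}
    atom_names: dict[int, str] = {}
    residue_names: dict[int, str] = {}
    residue_seqs: dict[int, int] = {}
    models = []
    for m, model in enumerate(structure, start=1):
        coords: dict[int, np.ndarray] = {}
        for chain in model:
            for residue in chain:
                for atom in residue:
                    key = (chain.name, residue.seqid.num, atom.name)
                    if key not in key_to_index:
                        if m > 1:
                            raise ValueError(
                                f"model {m} introduces new atom {key}")
                        idx = len(key_to_index) + 1
                        key_to_index[key] = idx
                        atom_names[idx] = atom.name
                        residue_names[idx] = residue.name
                        residue_seqs[idx] = residue.seqid.num
                    coords[key_to_index[key]] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z]) * A_TO_NM
        models.append(StructureModel(model_id=m, coordinates=coords))
    return Ensemble(models=models, atom_names=atom_names,
                    residue_names=residue_names, residue_seqs=residue_seqs)


def write_pdb(ensemble: Ensemble, chain_id: str = "A") -> str:
    """Serialize an ensemble as multi-model PDB text (coordinates in A)."""
    out = io.StringIO()
    for model in ensemble.models:
        out.write(f"MODEL     {model.model_id:4d}\n")
        for i in model.indices:
            x, y, z = model[i] / A_TO_NM
            name = ensemble.atom_names.get(i, "X")
            resname = ensemble.residue_names.get(i, "UNK")
            resseq = ensemble.residue_seqs.get(i, 1)
            pdb_name = f" {name:<3s}" if len(name) < 4 else name[:4]
            element = "H" if _is_hydrogen(name) else name[0]
            out.write(
                f"ATOM  {i:5d} {pdb_name}{'':1s}{resname:<4s}{chain_id}{resseq:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}\n")
        out.write("ENDMDL\n")
    out.write("END\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# GRO (single frame)
# ---------------------------------------------------------------------------

def read_gro(path: str | Path) -> Ensemble:
    """Read a GROMACS .gro coordinate file (one frame) into an Ensemble."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    coords: dict[int, np.ndarray] = {}
    atom_names: dict[int, str] = {}
    residue_names: dict[int, str] = {}
    residue_seqs: dict[int, int] = {}
    for k, atom in enumerate(u.atoms, start=1):
        coords[k] = atom.position * A_TO_NM  # MDAnalysis positions are in A
        atom_names[k] = atom.name
        residue_names[k] = atom.resname
        residue_seqs[k] = int(atom.resid)
    model = StructureModel(model_id=1, coordinates=coords)
    return Ensemble(models=[model], atom_names=atom_names,
                    residue_names=residue_names, residue_seqs=residue_seqs)


def read_structures(path: str | Path) -> Ensemble:
    """Dispatch on file suffix: .pdb (multi-model) or .gro."""
    path = Path(path)
    if path.suffix.lower() == ".gro":
        return read_gro(path)
    return read_pdb_models(path)
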