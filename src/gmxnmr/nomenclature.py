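"""Two-layer atom-name translation.

NMR depositions address magnetically equivalent protons with degenerate
group identifiers (pseudo-atoms: Ala MB, Leu MD1, Tyr QD, ...), and even
single protons are named after IUPAC conventions that predate biomolecular
force fields.  Converting a restraint therefore takes two steps:

1. expand the NMR identifier to the real atoms it denotes, and
2. rename those atoms to the scheme of the target force field
   (Amber or Charmm).

Both steps are driven by one packaged rule table
(``data/translations.tsv``); identifiers without a rule pass through
unchanged, so non-standard residues degrade to a warning downstream rather
than an error here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .records import AMINO_ACIDS, NUCLEOTIDES, AtomSpec, RawDihedralRecord

logger = logging.getLogger(__name__)

FORCE_FIELDS = ("amber", "charmm")


class DihedralTranslationError(ValueError):
    """A torsion restraint referenced a degenerate group."""


@dataclass(frozen=True)
class TranslationRule:
    residues: frozenset[str]
    identifier: str
    targets_amber: tuple[str, ...]
    targets_charmm: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.targets_amber or not self.targets_charmm:
            raise ValueError("translation targets must be non-empty")
        if len(self.targets_amber) != len(self.targets_charmm):
            raise ValueError("amber and charmm target lists must have equal length")

    def targets(self, force_field: str) -> tuple[str, ...]:
        return self.targets_amber if force_field == "amber" else self.targets_charmm


@dataclass(frozen=True)
class ExpandedAtom:
    """A concrete force-field atom together with the identifier it came from."""

    spec: AtomSpec
    origin: str


def normalize_identifier(identifier: str) -> str:
    """Upper-case and map typographic primes to ASCII (double prime -> '')."""
    return (identifier.replace("″", "''").replace("′", "'")
            .replace("’", "'").replace("”", "''").upper())


_GROUPS = {"PROTEIN": AMINO_ACIDS, "NUCLEIC": NUCLEOTIDES}


def load_rules(path: Optional[str | Path] = None) -> list[TranslationRule]:
    """Load translation rules from a TSV file (default: the packaged table)."""
    if path is None:
        text = (resources.files("gmxnmr") / "data" / "translations.tsv").read_text()
    else:
        text = Path(path).read_text()
    rules: list[TranslationRule] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"bad translation rule line: {line!r}")
        res_field, identifier, amber, charmm = fields
        residues: set[str] = set()
        for token in res_field.split(","):
            token = token.strip().upper()
            residues |= _GROUPS.get(token, {token})
        rules.append(TranslationRule(
            residues=frozenset(residues),
            identifier=normalize_identifier(identifier),
            targets_amber=tuple(a.strip() for a in amber.split(",")),
            targets_charmm=tuple(c.strip() for c in charmm.split(",")),
        ))
    return rules


class Translator:
    """Rule-table lookup with pass-through fallback."""

    def __init__(self, rules: Optional[Iterable[TranslationRule]] = None) -> None:
        self.rules = list(rules) if rules is not None else load_rules()
        self._index: dict[tuple[str, str], TranslationRule] = {}
        for rule in self.rules:
            for res in rule.residues:
                key = (res, rule.identifier)
                if key in self._index and self._index[key] != rule:
                    raise ValueError(f"conflicting rules for {key}")
                self._index[key] = rule

    def translate_atom(self, residue_name: str, identifier: str,
                       force_field: str) -> list[str]:
        """All real force-field atom names an NMR identifier denotes.

        Identifiers with no rule pass through unchanged as a singleton
        (logged at debug level so bulk conversions stay quiet).
        """
        if force_field not in FORCE_FIELDS:
            raise ValueError(f"unsupported force field {force_field!r}")
        res = residue_name.strip().upper()
        ident = normalize_identifier(identifier)
        rule = self._index.get((res, ident))
        if rule is None:
            logger.debug("no translation rule for %s %s; passing through", res, ident)
            return [ident]
        return list(rule.targets(force_field))

    def expand_pair(self, a: AtomSpec, b: AtomSpec,
                    force_field: str) -> list[tuple[ExpandedAtom, ExpandedAtom]]:
        """Cartesian product of the two expansions (outer a, inner b)."""
        names_a = self.translate_atom(a.residue_name, a.atom_id, force_field)
        names_b = self.translate_atom(b.residue_name, b.atom_id, force_field)
        pairs = []
        for na in names_a:
            ea = ExpandedAtom(spec=AtomSpec(a.chain_label, a.residue_seq,
                                            a.residue_name, na), origin=a.atom_id)
            for nb in names_b:
                eb = ExpandedAtom(spec=AtomSpec(b.chain_label, b.residue_seq,
                                                b.residue_name, nb), origin=b.atom_id)
                pairs.append((ea, eb))
        return pairs

    def translate_dihedral(self, record: RawDihedralRecord,
                           force_field: str) -> tuple[str, str, str, str]:
        """Four concrete atom names, in input order.

        Raises
        ------
        DihedralTranslationError
            If any identifier denotes more than one atom: a torsion is
            defined by four specific atoms, not by groups.
        """
        names = []
        for atom in record.atoms:
            targets = self.translate_atom(atom.residue_name, atom.atom_id, force_field)
            if len(targets) != 1:
                raise DihedralTranslationError(
                    f"dihedral restraint {record.restraint_id}: identifier "
                    f"{atom.atom_id} on {atom.residue_name} {atom.residue_seq} "
                    f"denotes {len(targets)} atoms"
                )
            names.append(targets[0])
        return tuple(names)


_DEFAULT: Optional[Translator] = None


def default_translator() -> Translator:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = Translator()
    return _DEFAULT


def translate_atom(residue_name: str, identifier: str, force_field: str) -> list[str]:
    return default_translator().translate_atom(residue_name, identifier, force_field)


def expand_pair(a: AtomSpec, b: AtomSpec, force_field: str):
    return default_translator().expand_pair(a, b, force_field)


def translate_dihedral(record: RawDihedralRecord, force_field: str):
    return default_translator().translate_dihedral(record, force_field)
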