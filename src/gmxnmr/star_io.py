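"""Read restraint loops from NMR-STAR v3 depositions.

NMR-STAR is the archival STAR dialect used by the BMRB/PDB for NMR data:
``data_`` blocks containing ``save_`` frames, which in turn hold tag/value
pairs and ``loop_`` tables.  Only the restraint tables are interpreted here:

* distance (NOE) constraints  — ``_Gen_dist_constraint`` loops (3.1 style)
  and simpler two-atom dialects with the same column vocabulary,
* torsion-angle constraints   — ``_Torsion_angle_constraint`` loops,
* residual dipolar couplings  — ``_RDC_constraint`` loops.

Rows of a distance loop that share one constraint ID are logical-OR
alternatives and become members of a single :class:`RawDistanceRecord`.
Bounds are kept in the deposited units (Angstrom, degrees); unit conversion
is the converter's job, not the reader's.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from .records import (
    AtomSpec,
    RawDihedralRecord,
    RawDistanceRecord,
    RawOrientationRecord,
    RestraintSets,
)

logger = logging.getLogger(__name__)

NULLS = {".", "?", ""}


class StarSyntaxError(ValueError):
    """Malformed STAR input; message names the offending save-frame."""


class RetrievalError(RuntimeError):
    """A deposition could not be fetched from the archive."""


# ---------------------------------------------------------------------------
# tokenizer / frame model
# ---------------------------------------------------------------------------

@dataclass
class Loop:
    tags: list[str]
    rows: list[list[str]]

    def column(self, *names: str) -> Optional[int]:
        """Index of the first tag whose part after the dot matches a name."""
        short = [t.split(".", 1)[-1].lower() for t in self.tags]
        for name in names:
            if name.lower() in short:
                return short.index(name.lower())
        return None

    @property
    def category(self) -> str:
        return self.tags[0].split(".", 1)[0].lstrip("_").lower() if self.tags else ""


@dataclass
class SaveFrame:
    name: str
    tags: dict[str, str] = field(default_factory=dict)
    loops: list[Loop] = field(default_factory=list)


def _tokenize(text: str) -> Iterator[tuple[str, bool]]:
    """Yield (token, was_quoted) pairs, honoring STAR quoting rules."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):  # semicolon-delimited text block
            block = [line[1:]]
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                block.append(lines[i])
                i += 1
            if i >= len(lines):
                raise StarSyntaxError("unterminated semicolon text block")
            yield "\n".join(block), True
            i += 1
            continue
        pos = 0
        n = len(line)
        while pos < n:
            while pos < n and line[pos] in " \t":
                pos += 1
            if pos >= n:
                break
            ch = line[pos]
            if ch == "#":
                break  # comment to end of line
            if ch in "'\"":
                # quoted value; closing quote must precede whitespace/EOL
                j = pos + 1
                while j < n:
                    if line[j] == ch and (j + 1 == n or line[j + 1] in " \t"):
                        break
                    j += 1
                if j >= n:
                    raise StarSyntaxError(f"unterminated quote in line: {line!r}")
                yield line[pos + 1:j], True
                pos = j + 1
            else:
                j = pos
                while j < n and line[j] not in " \t":
                    j += 1
                yield line[pos:j], False
                pos = j
        i += 1


def _parse_frames(text: str) -> list[SaveFrame]:
    """Parse STAR text into save-frames (top-level items get frame '')."""
    frames: list[SaveFrame] = []
    current = SaveFrame(name="")
    frames.append(current)
    toks = _tokenize(text)
    pending_tag: Optional[str] = None
    in_loop = False
    loop_tags: list[str] = []
    loop_values: list[str] = []

    def flush_loop() -> None:
        nonlocal in_loop, loop_tags, loop_values
        if not in_loop:
            return
        if loop_tags:
            width = len(loop_tags)
            if loop_values and len(loop_values) % width != 0:
                raise StarSyntaxError(
                    f"loop in save-frame '{current.name}' has "
                    f"{len(loop_values)} values for {width} tags"
                )
            rows = [loop_values[k:k + width] for k in range(0, len(loop_values), width)]
            current.loops.append(Loop(tags=loop_tags, rows=rows))
        in_loop = False
        loop_tags = []
        loop_values = []

    for tok, quoted in toks:
        low = tok.lower()
        if not quoted and (low.startswith("data_") or low == "global_"):
            flush_loop()
            continue
        if not quoted and low.startswith("save_"):
            flush_loop()
            if pending_tag is not None:
                raise StarSyntaxError(
                    f"tag {pending_tag} in save-frame '{current.name}' has no value"
                )
            if len(low) > len("save_"):
                current = SaveFrame(name=tok[len("save_"):])
                frames.append(current)
            else:  # bare save_ terminates the frame
                current = frames[0]
            continue
        if not quoted and low == "loop_":
            flush_loop()
            if pending_tag is not None:
                raise StarSyntaxError(
                    f"tag {pending_tag} in save-frame '{current.name}' has no value"
                )
            in_loop = True
            continue
        if not quoted and low == "stop_":
            flush_loop()
            continue
        if not quoted and tok.startswith("_"):
            if in_loop:
                if loop_values:
                    # tags after values begin a malformed header
                    raise StarSyntaxError(
                        f"tag {tok} inside loop body in save-frame '{current.name}'"
                    )
                loop_tags.append(tok)
            else:
                if pending_tag is not None:
                    raise StarSyntaxError(
                        f"tag {pending_tag} in save-frame '{current.name}' has no value"
                    )
                pending_tag = tok
            continue
        # plain or quoted value
        if in_loop:
            loop_values.append(tok)
        elif pending_tag is not None:
            current.tags[pending_tag] = tok
            pending_tag = None
        else:
            raise StarSyntaxError(
                f"stray value {tok!r} in save-frame '{current.name}'"
            )
    flush_loop()
    if pending_tag is not None:
        raise StarSyntaxError(
            f"tag {pending_tag} in save-frame '{current.name}' has no value"
        )
    return frames


# ---------------------------------------------------------------------------
# restraint extraction
# ---------------------------------------------------------------------------

_DIST_CATEGORIES = re.compile(r"(gen_dist_constraint|dist_constraint|distance_constraint)$")


def _get(row: Sequence[str], col: Optional[int]) -> Optional[str]:
    if col is None:
        return None
    v = row[col]
    return None if v in NULLS else v


def _atom_from_row(loop: Loop, row: Sequence[str], suffix: str) -> Optional[AtomSpec]:
    """Build an AtomSpec from a row's *_1 / *_2 / ... columns."""
    chain = _get(row, loop.column(f"entity_assembly_id{suffix}",
                                  f"auth_asym_id{suffix}")) or "A"
    seq = _get(row, loop.column(f"auth_seq_id{suffix}",
                                f"comp_index_id{suffix}", f"seq_id{suffix}"))
    name = _get(row, loop.column(f"comp_id{suffix}", f"auth_comp_id{suffix}"))
    atom = _get(row, loop.column(f"atom_id{suffix}", f"auth_atom_id{suffix}"))
    if seq is None or name is None or atom is None:
        return None
    return AtomSpec(chain_label=chain, residue_seq=int(seq),
                    residue_name=name.upper(), atom_id=atom)


def _float(value: Optional[str]) -> Optional[float]:
    if value is None:
        return None
    return float(value)


def _extract_distances(loop: Loop, frame: SaveFrame, sets: RestraintSets) -> None:
    id_col = loop.column("id", "index_id")
    groups: dict[int, dict] = {}
    order: list[int] = []
    for rownum, row in enumerate(loop.rows, start=1):
        try:
            rid = int(row[id_col]) if id_col is not None else rownum
            a = _atom_from_row(loop, row, "_1")
            b = _atom_from_row(loop, row, "_2")
            if a is None or b is None:
                raise ValueError("incomplete atom address")
            lower = _float(_get(row, loop.column("distance_lower_bound_val",
                                                 "lower_bound", "dist_lower_bound_val")))
            upper = _float(_get(row, loop.column("distance_upper_bound_val",
                                                 "upper_bound", "dist_upper_bound_val")))
            target = _float(_get(row, loop.column("distance_val", "target_val", "dist_val")))
            err = _float(_get(row, loop.column("distance_val_err", "target_val_err",
                                               "dist_val_err")))
            # (target, +/- tolerance) depositions -> explicit bounds, here only
            if upper is None and target is not None:
                upper = target + (err or 0.0)
            if lower is None:
                lower = max(0.0, target - err) if (target is not None and err is not None) else 0.0
            if upper is None:
                raise ValueError("no upper bound")
        except (ValueError, IndexError) as exc:
            msg = (f"distance row {rownum} in save-frame '{frame.name}' skipped: {exc}")
            logger.warning(msg)
            sets.warnings.append(msg)
            continue
        if rid not in groups:
            groups[rid] = {"members": [], "lower": lower, "upper": upper, "target": target}
            order.append(rid)
        groups[rid]["members"].append((a, b))
    base = max((r.restraint_id for r in sets.distances), default=0)
    for rid in order:
        g = groups[rid]
        sets.distances.append(RawDistanceRecord(
            restraint_id=base + rid if base else rid,
            members=g["members"],
            lower_bound=g["lower"],
            upper_bound=g["upper"],
            target=g["target"],
        ))


def _extract_dihedrals(loop: Loop, frame: SaveFrame, sets: RestraintSets) -> None:
    id_col = loop.column("id", "index_id")
    name_col = loop.column("torsion_angle_name", "angle_name")
    base = max((r.restraint_id for r in sets.dihedrals), default=0)
    for rownum, row in enumerate(loop.rows, start=1):
        try:
            rid = int(row[id_col]) if id_col is not None else rownum
            atoms = tuple(_atom_from_row(loop, row, f"_{k}") for k in range(1, 5))
            if any(a is None for a in atoms):
                raise ValueError("incomplete atom address")
            lower = _float(_get(row, loop.column("angle_lower_bound_val", "angle_lower_bound")))
            upper = _float(_get(row, loop.column("angle_upper_bound_val", "angle_upper_bound")))
            if lower is None or upper is None:
                raise ValueError("missing angle bound")
            record = RawDihedralRecord(
                restraint_id=base + rid,
                atoms=atoms,
                angle_lower=lower,
                angle_upper=upper,
                angle_name=(_get(row, name_col) or "UNKNOWN").upper(),
            )
        except (ValueError, IndexError) as exc:
            msg = f"dihedral row {rownum} in save-frame '{frame.name}' skipped: {exc}"
            logger.warning(msg)
            sets.warnings.append(msg)
            continue
        sets.dihedrals.append(record)


def _extract_rdcs(loop: Loop, frame: SaveFrame, sets: RestraintSets,
                  experiment_id: int) -> None:
    id_col = loop.column("id", "index_id")
    base = max((r.restraint_id for r in sets.orientations), default=0)
    for rownum, row in enumerate(loop.rows, start=1):
        try:
            rid = int(row[id_col]) if id_col is not None else rownum
            a = _atom_from_row(loop, row, "_1")
            b = _atom_from_row(loop, row, "_2")
            if a is None or b is None:
                raise ValueError("incomplete atom address")
            obs = _float(_get(row, loop.column("rdc_val", "val")))
            if obs is None:
                raise ValueError("missing coupling value")
            err = _float(_get(row, loop.column("rdc_val_err", "val_err")))
            record = RawOrientationRecord(
                restraint_id=base + rid,
                atoms=(a, b),
                observed=obs,
                error=err,
                experiment_id=experiment_id,
            )
        except (ValueError, IndexError) as exc:
            msg = f"RDC row {rownum} in save-frame '{frame.name}' skipped: {exc}"
            logger.warning(msg)
            sets.warnings.append(msg)
            continue
        sets.orientations.append(record)


def parse_star(star_text: str, source_label: str = "") -> RestraintSets:
    """Parse NMR-STAR content into :class:`RestraintSets`.

    Absent restraint loops yield empty lists.  Rows with unparsable content
    are skipped, logged, and counted in ``RestraintSets.warnings``.

    Raises
    ------
    StarSyntaxError
        On malformed STAR syntax, naming the save-frame where possible.
    """
    frames = _parse_frames(star_text)
    sets = RestraintSets(source_label=source_label)
    rdc_experiment = 0
    for frame in frames:
        frame_rdc_counted = False
        for loop in frame.loops:
            cat = loop.category
            if _DIST_CATEGORIES.search(cat) and loop.column("atom_id_1") is not None:
                _extract_distances(loop, frame, sets)
            elif cat.endswith("torsion_angle_constraint"):
                _extract_dihedrals(loop, frame, sets)
            elif cat.endswith("rdc_constraint"):
                if not frame_rdc_counted:
                    rdc_experiment += 1
                    frame_rdc_counted = True
                _extract_rdcs(loop, frame, sets, experiment_id=rdc_experiment)
    return sets


def parse_star_file(path: str | Path) -> RestraintSets:
    path = Path(path)
    return parse_star(path.read_text(), source_label=path.name)


# ---------------------------------------------------------------------------
# archive retrieval
# ---------------------------------------------------------------------------

RCSB_BASE = "https://files.rcsb.org/download"


def fetch_entry(pdb_id: str, cache_dir: str | Path | None = None,
                timeout: float = 30.0) -> tuple[str, str]:
    """Download the NMR-STAR restraint file and PDB coordinates for an entry.

    Returns ``(star_text, pdb_text)``.  Successful downloads are cached in
    ``cache_dir`` (default ``~/.cache/gmxnmr``); a failed download never
    leaves a partial cache file.

    Raises
    ------
    RetrievalError
        For malformed ids, unknown entries, or network failures.
    """
    import requests

    pdb_id = pdb_id.strip().lower()
    if not re.fullmatch(r"[0-9][a-z0-9]{3}", pdb_id):
        raise RetrievalError(f"not a valid PDB id: {pdb_id!r}")
    cache = Path(cache_dir) if cache_dir else Path.home() / ".cache" / "gmxnmr"
    cache.mkdir(parents=True, exist_ok=True)

    payloads = []
    for suffix in (f"{pdb_id}_mr.str", f"{pdb_id}.pdb"):
        cached = cache / suffix
        if cached.exists():
            payloads.append(cached.read_text())
            continue
        url = f"{RCSB_BASE}/{suffix}"
        try:
            resp = requests.get(url, timeout=timeout)
        except requests.RequestException as exc:
            raise RetrievalError(f"download of {url} failed: {exc}") from exc
        if resp.status_code != 200:
            raise RetrievalError(f"{url}: HTTP {resp.status_code}")
        text = resp.text
        if not text.strip():
            raise RetrievalError(f"{url}: empty payload")
        cached.write_text(text)
        payloads.append(text)
    return payloads[0], payloads[1]
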