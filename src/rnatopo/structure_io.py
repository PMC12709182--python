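"""Reading RNA 3D structures and deriving residue–residue contact maps.

A *contact map* is a binary, symmetric relation on the residue indices
``1..L`` marking pairs whose defining atoms lie within a distance threshold.
Two definitions are supported:

``nitrogen``
    Two residues are in contact if their glycosidic-face nitrogen atoms
    (N9 for purines A/G, N1 for pyrimidines C/U) are no more than 9.5 Å
    apart (inclusive).
``heavy``
    Two residues are in contact if their closest pair of non-hydrogen
    atoms is strictly less than 10 Å apart.

Near-diagonal pairs with sequence separation below ``min_sep`` (default 4)
are excluded as trivial; contacts are stored as upper-triangle pairs
``(i, j)`` with ``i < j``, 1-based.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DomainError,
    EmptyStructureError,
    FormatError,
    MalformedRecordError,
    MissingAtomError,
    UnknownResidueError,
)

__all__ = [
    "Residue",
    "RnaStructure",
    "ContactDefinition",
    "ContactMap",
    "WeightedContactMap",
    "MODIFIED_RESIDUES",
    "canonical_residue",
    "reference_atom",
    "read_pdb_structure",
    "extract_contact_map",
    "read_contact_table",
    "write_contact_table",
    "read_weighted_contact_table",
]

#: Standard ribonucleotides.
STANDARD_RESIDUES = ("A", "U", "C", "G")

#: Editable mapping of common modified-residue names to their parent
#: nucleotide.  Unmapped names raise :class:`UnknownResidueError` rather
#: than being guessed.
MODIFIED_RESIDUES: dict[str, str] = {
    "PSU": "U",  # pseudouridine
    "H2U": "U",  # dihydrouridine
    "5MU": "U",  # ribothymidine
    "4SU": "U",  # 4-thiouridine
    "OMU": "U",
    "5MC": "C",
    "OMC": "C",
    "1MA": "A",
    "2MG": "G",
    "M2G": "G",
    "7MG": "G",
    "OMG": "G",
    "I": "G",  # inosine pairs like G for the N9 reference
}


def canonical_residue(name: str, table: Mapping[str, str] | None = None) -> str:
    """Resolve a residue name to one of A, U, C, G.

    Parameters
    ----------
    name:
        Residue name as found in the coordinate file (e.g. ``"G"``,
        ``"PSU"``).
    table:
        Optional replacement for :data:`MODIFIED_RESIDUES`.
    """
    key = name.strip().upper()
    if key in STANDARD_RESIDUES:
        return key
    lookup = MODIFIED_RESIDUES if table is None else table
    if key in lookup:
        parent = lookup[key].strip().upper()
        if parent in STANDARD_RESIDUES:
            return parent
    raise UnknownResidueError(
        f"residue name {name!r} is not a standard nucleotide and has no "
        f"modified-residue mapping"
    )


def reference_atom(residue_name: str, table: Mapping[str, str] | None = None) -> str:
    """Name of the glycosidic nitrogen used as the residue reference point.

    Purines (A, G) use N9; pyrimidines (C, U) use N1.
    """
    base = canonical_residue(residue_name, table)
    return "N9" if base in ("A", "G") else "N1"


@dataclass(frozen=True)
class Residue:
    """One RNA residue with named-atom coordinates in Å."""

    chain: str
    position: int
    name: str
    atoms: Mapping[str, np.ndarray]
    hydrogens: frozenset[str] = frozenset()

    def heavy_atoms(self) -> dict[str, np.ndarray]:
        """Atoms excluding hydrogens (hydrogens are retained but flagged)."""
        return {n: c for n, c in self.atoms.items() if n not in self.hydrogens}


@dataclass(frozen=True)
class RnaStructure:
    """An ordered RNA molecule: residues with 3D coordinates.

    Residues are ordered by (chain, position) in file order; the ordinal
    1..L over this list is the index domain of every derived contact map.
    Original chain identifiers and author residue numbers are retained on
    each :class:`Residue`.
    """

    id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise EmptyStructureError(f"structure {self.id!r} has no residues")
        prev: dict[str, int] = {}
        for res in self.residues:
            if not res.atoms:
                raise FormatError(
                    f"residue {res.chain}/{res.position} has no atoms"
                )
            for name, coord in res.atoms.items():
                if not np.all(np.isfinite(coord)):
                    raise FormatError(
                        f"non-finite coordinate for atom {name} in residue "
                        f"{res.chain}/{res.position}"
                    )
            if res.chain in prev and res.position <= prev[res.chain]:
                raise FormatError(
                    f"residue positions do not strictly increase in chain "
                    f"{res.chain!r} at {res.position}"
                )
            prev[res.chain] = res.position

    @property
    def L(self) -> int:
        return len(self.residues)

    def sequence(self, table: Mapping[str, str] | None = None) -> str:
        """Canonical one-letter sequence (modified residues mapped)."""
        return "".join(canonical_residue(r.name, table) for r in self.residues)


@dataclass(frozen=True)
class ContactDefinition:
    """How a residue pair qualifies as a contact.

    ``threshold`` defaults to 9.5 Å in nitrogen mode and 10.0 Å in heavy
    mode.  The comparison is inclusive (≤) for the nitrogen definition and
    strict (<) for the heavy-atom definition; pass ``inclusive`` to
    override.  ``min_sep`` is the minimum sequence separation |i−j|.
    """

    mode: str = "nitrogen"
    threshold: float | None = None
    min_sep: int = 4
    inclusive: bool | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("nitrogen", "heavy"):
            raise DomainError(f"unknown contact mode {self.mode!r}")
        if self.threshold is None:
            object.__setattr__(
                self, "threshold", 9.5 if self.mode == "nitrogen" else 10.0
            )
        if self.threshold <= 0:
            raise DomainError("contact threshold must be positive")
        if self.min_sep < 1:
            raise DomainError("min_sep must be >= 1")
        if self.inclusive is None:
            object.__setattr__(self, "inclusive", self.mode == "nitrogen")

    def admits(self, distance: float) -> bool:
        return distance <= self.threshold if self.inclusive else distance < self.threshold


@dataclass(frozen=True)
class ContactMap:
    """A set of residue-index contact pairs on ``1..L``.

    Pairs are stored as upper-triangle representatives ``(i, j)`` with
    ``i < j``; the symmetric partner is implied.  ``definition`` is either
    the :class:`ContactDefinition` the map was derived under or the string
    ``"external"`` for maps read from tables or generated synthetically.
    """

    L: int
    contacts: frozenset[tuple[int, int]]
    definition: ContactDefinition | str = "external"
    min_sep: int | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise DomainError("contact map length L must be >= 1")
        if self.min_sep is None:
            sep = (
                self.definition.min_sep
                if isinstance(self.definition, ContactDefinition)
                else 4
            )
            object.__setattr__(self, "min_sep", sep)
        pairs = frozenset((int(i), int(j)) for i, j in self.contacts)
        for i, j in pairs:
            if not (1 <= i < j <= self.L):
                raise DomainError(f"contact ({i}, {j}) outside 1 <= i < j <= L={self.L}")
            if j - i < self.min_sep:
                raise DomainError(
                    f"contact ({i}, {j}) violates min_sep={self.min_sep}"
                )
        object.__setattr__(self, "contacts", pairs)

    def __len__(self) -> int:
        return len(self.contacts)

    def sorted_contacts(self) -> list[tuple[int, int]]:
        return sorted(self.contacts)

    def positions(self) -> np.ndarray:
        """(|C|, 2) float array of upper-triangle positions, sorted."""
        return np.asarray(self.sorted_contacts(), dtype=float)


@dataclass(frozen=True)
class WeightedContactMap:
    """Real-valued contact scores in [0, 1] on the upper triangle."""

    L: int
    weights: Mapping[tuple[int, int], float]
    min_sep: int = 1

    def __post_init__(self) -> None:
        if self.L < 1:
            raise DomainError("L must be >= 1")
        norm: dict[tuple[int, int], float] = {}
        for (i, j), w in self.weights.items():
            i, j = int(i), int(j)
            if not (1 <= i < j <= self.L):
                raise DomainError(f"cell ({i}, {j}) outside the upper triangle of L={self.L}")
            w = float(w)
            if not (0.0 <= w <= 1.0):
                raise DomainError(f"weight {w} at ({i}, {j}) outside [0, 1]")
            norm[(i, j)] = w
        object.__setattr__(self, "weights", norm)


# ---------------------------------------------------------------------------
# PDB / mmCIF reading
# ---------------------------------------------------------------------------

def _looks_like_mmcif(text: str) -> bool:
    head = text[:4000]
    return "_atom_site." in head or head.lstrip().startswith("data_")


def _resolve_source(source: str | Path | TextIO) -> tuple[str, str]:
    """Return (text, label) for a path, raw text, or file handle."""
    if hasattr(source, "read"):
        return source.read(), getattr(source, "name", "<stream>")
    if isinstance(source, Path):
        return source.read_text(), source.stem
    if "\n" in source:
        return source, "<text>"
    path = Path(source)
    if not path.exists():
        raise FormatError(f"structure source {source!r} is neither a file nor PDB text")
    return path.read_text(), path.stem


def _pick_altloc(atom):
    """Resolve a possibly disordered atom to its highest-occupancy child."""
    if atom.is_disordered():
        children = atom.disordered_get_list()
        return max(children, key=lambda a: ((a.get_occupancy() or 0.0), -ord(a.get_altloc() or " ")))
    return atom


def read_pdb_structure(
    source: str | Path | TextIO,
    chain: str | None = None,
    modified_table: Mapping[str, str] | None = None,
    structure_id: str | None = None,
) -> RnaStructure:
    """Read an RNA structure from PDB or mmCIF.

    Non-RNA residues (protein, water, ligands) are skipped silently;
    residues mapping to A/U/C/G directly or via the modified-residue table
    are kept.  Only the first model of a multi-model entry is used.
    Alternate locations are resolved to the highest-occupancy conformer,
    and hydrogens are retained but flagged.

    Parameters
    ----------
    source:
        Path to a file, raw file text, or an open text handle.
    chain:
        If given, keep only this chain.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    text, label = _resolve_source(source)
    handle = io.StringIO(text)
    try:
        if _looks_like_mmcif(text):
            model0 = next(MMCIFParser(QUIET=True).get_structure(label, handle).get_models())
        else:
            model0 = next(PDBParser(QUIET=True).get_structure(label, handle).get_models())
    except StopIteration:
        raise EmptyStructureError(f"{label}: no models found")
    except Exception as exc:  # Bio.PDB raises bare ValueError/KeyError on bad input
        raise FormatError(f"{label}: could not parse structure ({exc})") from exc

    residues: list[Residue] = []
    for ch in model0:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            hetflag, resseq, icode = res.get_id()
            resname = res.get_resname().strip()
            try:
                canonical_residue(resname, modified_table)
            except UnknownResidueError:
                continue
            atoms: dict[str, np.ndarray] = {}
            hydrogens: set[str] = set()
            for raw_atom in res:
                atom = _pick_altloc(raw_atom)
                name = atom.get_name()
                atoms[name] = np.asarray(atom.get_coord(), dtype=float)
                if (atom.element or "").upper() in ("H", "D"):
                    hydrogens.add(name)
            if atoms:
                residues.append(
                    Residue(
                        chain=str(ch.id),
                        position=int(resseq),
                        name=resname,
                        atoms=atoms,
                        hydrogens=frozenset(hydrogens),
                    )
                )
    if not residues:
        raise EmptyStructureError(f"{label}: no RNA residues found")
    return RnaStructure(id=structure_id or label, residues=tuple(residues))


# ---------------------------------------------------------------------------
# Contact extraction
# ---------------------------------------------------------------------------

def extract_contact_map(
    structure: RnaStructure,
    definition: ContactDefinition | None = None,
    modified_table: Mapping[str, str] | None = None,
) -> ContactMap:
    """Derive the contact map of a structure under a contact definition.

    In nitrogen mode the defining distance is between the N1/N9 reference
    atoms; in heavy mode it is the minimum over all non-hydrogen atom
    pairs of the two residues.
    """
    definition = definition or ContactDefinition()
    L = structure.L
    contacts: set[tuple[int, int]] = set()

    if definition.mode == "nitrogen":
        coords = np.empty((L, 3))
        for idx, res in enumerate(structure.residues):
            ref = reference_atom(res.name, modified_table)
            if ref not in res.atoms:
                raise MissingAtomError(
                    f"residue {res.chain}/{res.position} ({res.name}) lacks "
                    f"reference atom {ref}"
                )
            coords[idx] = res.atoms[ref]
        dist = squareform(pdist(coords))
        for i in range(L):
            for j in range(i + definition.min_sep, L):
                if definition.admits(dist[i, j]):
                    contacts.add((i + 1, j + 1))
    else:
        atom_coords: list[np.ndarray] = []
        atom_owner: list[int] = []
        for idx, res in enumerate(structure.residues):
            heavy = res.heavy_atoms()
            if not heavy:
                raise MissingAtomError(
                    f"residue {res.chain}/{res.position} has no heavy atoms"
                )
            for coord in heavy.values():
                atom_coords.append(coord)
                atom_owner.append(idx)
        pts = np.asarray(atom_coords)
        owner = np.asarray(atom_owner)
        tree = cKDTree(pts)
        # query_pairs is closed (<= r); exact distances are re-checked below
        # so the strict/inclusive comparison is honoured either way.
        best: dict[tuple[int, int], float] = {}
        for a, b in tree.query_pairs(r=definition.threshold):
            ri, rj = owner[a], owner[b]
            if ri == rj:
                continue
            key = (min(ri, rj) + 1, max(ri, rj) + 1)
            if key[1] - key[0] < definition.min_sep:
                continue
            d = float(np.linalg.norm(pts[a] - pts[b]))
            if key not in best or d < best[key]:
                best[key] = d
        contacts = {pair for pair, d in best.items() if definition.admits(d)}

    return ContactMap(L=L, contacts=frozenset(contacts), definition=definition)


# ---------------------------------------------------------------------------
# Contact tables ("i j [score]" plain text)
# ---------------------------------------------------------------------------

def _header_metadata(cmap: ContactMap) -> list[str]:
    lines = [f"# L={cmap.L}", f"# min_sep={cmap.min_sep}"]
    if isinstance(cmap.definition, ContactDefinition):
        d = cmap.definition
        lines.insert(1, f"# mode={d.mode} threshold={d.threshold} inclusive={d.inclusive}")
    else:
        lines.insert(1, f"# mode={cmap.definition}")
    return lines


def _parse_header(lines: Iterable[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        for token in line.lstrip("#").split():
            if "=" in token:
                key, _, value = token.partition("=")
                meta[key] = value
    return meta


def _read_records(
    text: str, L: int | None, min_sep: int | None, want_scores: bool
):
    comment_lines = []
    records: list[tuple[int, tuple[int, int], float]] = []
    max_j = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comment_lines.append(line)
            continue
        fields = line.split()
        if len(fields) not in (2, 3):
            raise MalformedRecordError(f"line {lineno}: expected 'i j [score]', got {raw!r}")
        try:
            i, j = int(fields[0]), int(fields[1])
            score = float(fields[2]) if len(fields) == 3 else 1.0
        except ValueError:
            raise MalformedRecordError(f"line {lineno}: non-numeric field in {raw!r}")
        if i == j:
            raise MalformedRecordError(f"line {lineno}: self-contact ({i}, {j})")
        if i < 1 or j < 1:
            raise MalformedRecordError(f"line {lineno}: indices must be >= 1")
        pair = (min(i, j), max(i, j))
        max_j = max(max_j, pair[1])
        records.append((lineno, pair, score))

    meta = _parse_header(comment_lines)
    if L is None:
        L = int(meta["L"]) if "L" in meta else max_j
    if min_sep is None:
        min_sep = int(meta.get("min_sep", 1))
    for lineno, (i, j), _ in records:
        if j > L:
            raise MalformedRecordError(f"line {lineno}: index {j} exceeds L={L}")
        if j - i < min_sep:
            raise MalformedRecordError(
                f"line {lineno}: pair ({i}, {j}) violates min_sep={min_sep}"
            )
    return records, L, min_sep


def read_contact_table(
    source: str | Path | TextIO,
    L: int | None = None,
    min_sep: int | None = None,
) -> ContactMap:
    """Read a plain-text contact table ("i j [score]" per line).

    Lines are whitespace-separated, 1-based; ``#`` starts a comment.  Pairs
    are normalized to ``i < j`` and duplicates collapsed.  ``L`` and
    ``min_sep`` are taken from the arguments, else from ``key=value``
    header comments, else inferred (``L`` from the largest index,
    ``min_sep`` = 1).
    """
    text, _ = _resolve_source(source)
    records, L, min_sep = _read_records(text, L, min_sep, want_scores=False)
    pairs = frozenset(pair for _, pair, _ in records)
    return ContactMap(L=L, contacts=pairs, definition="external", min_sep=min_sep)


def read_weighted_contact_table(
    source: str | Path | TextIO,
    L: int | None = None,
    min_sep: int | None = None,
) -> WeightedContactMap:
    """Read an "i j score" table as a weighted contact map (scores in [0,1])."""
    text, _ = _resolve_source(source)
    records, L, min_sep = _read_records(text, L, min_sep, want_scores=True)
    weights: dict[tuple[int, int], float] = {}
    for _, pair, score in records:
        weights[pair] = max(weights.get(pair, 0.0), score)
    return WeightedContactMap(L=L, weights=weights, min_sep=min_sep)


def write_contact_table(cmap: ContactMap, sink: str | Path | TextIO | None = None) -> str:
    """Write a contact map as plain text; returns the text.

    The header records the contact definition (mode, threshold, min_sep)
    so that ``read_contact_table(write_contact_table(m)) == m``.
    """
    lines = _header_metadata(cmap)
    lines.extend(f"{i} {j}" for i, j in cmap.sorted_contacts())
    text = "\n".join(lines) + "\n"
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            Path(sink).write_text(text)
    return text
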