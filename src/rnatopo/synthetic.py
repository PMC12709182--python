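"""Download-free generators of RNA-like structures, contact maps, and
RMSD tables.

These generators emulate just enough geometry and topology to exercise
every operation in the toolkit: idealized hairpin stems whose paired
reference atoms sit within the nitrogen contact threshold, contact maps
built from anti-diagonal stem runs plus blob-like tertiary patches (the
clustered topology characteristic of convolutional contact predictors),
and RMSD tables with a controlled improvement probability.  They make no
claim to thermodynamic or physical realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DomainError
from .evaluation import RmsdTable
from .structure_io import ContactMap, Residue, RnaStructure

__all__ = [
    "ToyStructure",
    "generate_toy_structure",
    "generate_synthetic_contact_map",
    "generate_rmsd_table",
    "pdb_text",
    "make_fixture_tree",
]

_RISE = 3.1       # Å between consecutive stem residues
_PAIR_DIST = 8.5  # Å between paired reference atoms (inside the 9.5 Å threshold)
_LOOP_OFFSET = 12.0  # Å sideways displacement keeping loops out of contact range


@dataclass(frozen=True)
class ToyStructure:
    """A generated structure together with its ground-truth base pairing."""

    structure: RnaStructure
    pairing: tuple[tuple[int, int], ...]


def _as_lengths(value: int | Sequence[int], count: int, what: str) -> list[int]:
    if isinstance(value, int):
        return [value] * count
    lengths = list(value)
    if len(lengths) != count:
        raise DomainError(f"expected {count} {what}, got {len(lengths)}")
    return lengths


def generate_toy_structure(
    n_helices: int = 1,
    helix_length: int | Sequence[int] = 5,
    loop_length: int | Sequence[int] = 4,
    seed: int | None = 0,
    jitter: float = 0.05,
    structure_id: str = "toy",
) -> ToyStructure:
    """Build an idealized RNA-like structure of hairpin stems.

    Each helix is a ladder of G–C pairs: the two strands run antiparallel
    with paired reference atoms 8.5 Å apart (inside the 9.5 Å nitrogen
    threshold), joined by a hairpin loop displaced sideways so loop
    residues create no stem contacts.  Helices are strung in series far
    apart.  With ``n_helices=0`` an extended chain of ``loop_length``
    residues is produced (no admissible contacts at min_sep 4).

    Hairpin loops must have >= 3 residues so the innermost pair clears the
    default minimum sequence separation of 4; shorter requests are
    geometrically infeasible here and raise.

    Returns the structure and the designed pairing list; extraction
    recovers at least the designed pairs (plus geometric neighbours from
    the ladder).
    """
    if n_helices < 0:
        raise DomainError("n_helices must be >= 0")
    rng = np.random.default_rng(seed)

    residues: list[Residue] = []
    pairing: list[tuple[int, int]] = []

    def add_residue(name: str, point: np.ndarray) -> int:
        point = point + rng.normal(0.0, jitter, size=3)
        ref = "N9" if name in ("A", "G") else "N1"
        atoms = {ref: point, "C1'": point + np.array([0.0, 1.5, 0.0])}
        residues.append(
            Residue(chain="A", position=len(residues) + 1, name=name, atoms=atoms)
        )
        return len(residues)

    if n_helices == 0:
        length = loop_length if isinstance(loop_length, int) else sum(loop_length)
        if length < 1:
            raise DomainError("an extended chain needs >= 1 residue")
        for k in range(length):
            add_residue("A", np.array([7.0 * k, 0.0, 0.0]))
        return ToyStructure(
            structure=RnaStructure(id=structure_id, residues=tuple(residues)),
            pairing=(),
        )

    helix_lengths = _as_lengths(helix_length, n_helices, "helix lengths")
    loop_lengths = _as_lengths(loop_length, n_helices, "loop lengths")
    for hl, ll in zip(helix_lengths, loop_lengths):
        if hl < 1:
            raise DomainError("helix length must be >= 1")
        if ll < 3:
            raise DomainError(
                "hairpin loops need >= 3 residues for the innermost pair to "
                "clear the minimum sequence separation"
            )

    for h in range(n_helices):
        hl, ll = helix_lengths[h], loop_lengths[h]
        x0 = 60.0 * h
        z_top = _RISE * (hl - 1)
        strand1 = [
            add_residue("G", np.array([x0, 0.0, _RISE * k])) for k in range(hl)
        ]
        for j in range(1, ll + 1):
            add_residue(
                "A",
                np.array([x0 + _PAIR_DIST * j / (ll + 1), _LOOP_OFFSET, z_top + 4.0]),
            )
        for k in range(hl):
            partner = strand1[hl - 1 - k]
            idx = add_residue("C", np.array([x0 + _PAIR_DIST, 0.0, _RISE * (hl - 1 - k)]))
            pairing.append((partner, idx))
        if h < n_helices - 1:
            span = 60.0 - _PAIR_DIST
            for j in range(1, ll + 1):
                add_residue(
                    "U",
                    np.array(
                        [x0 + _PAIR_DIST + span * j / (ll + 1), -_LOOP_OFFSET, 0.0]
                    ),
                )

    return ToyStructure(
        structure=RnaStructure(id=structure_id, residues=tuple(residues)),
        pairing=tuple(sorted(pairing)),
    )


def generate_synthetic_contact_map(
    L: int,
    stems: Sequence[tuple[int, int, int]] = (),
    patches: Sequence[tuple[tuple[int, int], int, float]] = (),
    seed: int | None = 0,
    min_sep: int = 4,
) -> ContactMap:
    """Plant stems and tertiary patches on an L x L contact map.

    A stem ``(s_i, s_j, length)`` contributes the anti-diagonal run
    ``(s_i + k, s_j - k)`` for ``k < length`` — the signature of an RNA
    helix.  A patch ``(center, radius, density)`` adds Bernoulli(density)
    cells within Euclidean ``radius`` of its center, emulating the blobs
    of clustered predictor output.  Stem cells must lie fully inside the
    admissible domain and must not overlap each other; patch centers must
    be in-domain, with candidate cells clipped to the domain.
    """
    if L < 1:
        raise DomainError("L must be >= 1")
    rng = np.random.default_rng(seed)

    def in_domain(i: int, j: int) -> bool:
        return 1 <= i < j <= L and j - i >= min_sep

    cells: set[tuple[int, int]] = set()
    for s_i, s_j, length in stems:
        if length < 1:
            raise DomainError("stem length must be >= 1")
        for k in range(length):
            cell = (s_i + k, s_j - k)
            if not in_domain(*cell):
                raise DomainError(
                    f"stem ({s_i}, {s_j}, {length}) leaves the admissible domain at {cell}"
                )
            if cell in cells:
                raise DomainError(f"stem cell {cell} overlaps a previous stem")
            cells.add(cell)

    for (ci, cj), radius, density in patches:
        if not in_domain(ci, cj):
            raise DomainError(f"patch center ({ci}, {cj}) outside the admissible domain")
        if radius < 0:
            raise DomainError("patch radius must be >= 0")
        if not (0.0 <= density <= 1.0):
            raise DomainError("patch density must lie in [0, 1]")
        for di in range(-radius, radius + 1):
            for dj in range(-radius, radius + 1):
                if di * di + dj * dj > radius * radius:
                    continue
                cell = (ci + di, cj + dj)
                if in_domain(*cell) and rng.random() < density:
                    cells.add(cell)

    return ContactMap(L=L, contacts=frozenset(cells), definition="external", min_sep=min_sep)


def generate_rmsd_table(
    n_molecules: int,
    improve_probability: float = 0.7,
    L_range: tuple[int, int] = (30, 300),
    effect: float = 2.0,
    seed: int | None = 0,
) -> RmsdTable:
    """Synthesize per-molecule restrained/unrestrained RMSD pairs.

    Unrestrained RMSDs are drawn uniformly from 4–30 Å (the span observed
    across typical fragment- and Monte-Carlo-based folding runs); with
    probability ``improve_probability`` the restrained value is lower by
    ``effect`` Å (floored at 0), otherwise higher by the same amount.
    """
    if not (0.0 <= improve_probability <= 1.0):
        raise DomainError("improve_probability must lie in [0, 1]")
    if effect < 0:
        raise DomainError("effect size must be >= 0")
    if n_molecules < 1:
        raise DomainError("need at least one molecule")
    lo, hi = L_range
    if not (1 <= lo <= hi):
        raise DomainError("invalid L_range")
    rng = np.random.default_rng(seed)
    free = rng.uniform(4.0, 30.0, size=n_molecules)
    improved = rng.random(n_molecules) < improve_probability
    restrained = np.where(improved, np.clip(free - effect, 0.0, None), free + effect)
    lengths = rng.integers(lo, hi + 1, size=n_molecules)
    rows = [
        (f"mol{k:04d}", int(lengths[k]), float(restrained[k]), float(free[k]))
        for k in range(n_molecules)
    ]
    return RmsdTable.from_rows(rows)


# ---------------------------------------------------------------------------
# Fixture materialization
# ---------------------------------------------------------------------------

def pdb_text(structure: RnaStructure) -> str:
    """Render a structure as minimal PDB ATOM records (fixture output)."""
    lines = []
    serial = 0
    for res in structure.residues:
        for name, coord in res.atoms.items():
            serial += 1
            element = "H" if name in res.hydrogens else name[0]
            atom_field = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {atom_field:4s} {res.name:>3s} {res.chain[:1]}"
                f"{res.position:4d}    {coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_fixture_tree(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Materialize a standard tree of plain-text fixtures.

    Writes a toy hairpin PDB, its extracted native contact table, a
    planted-topology synthetic contact map, and a synthetic RMSD table.
    """
    from .structure_io import ContactDefinition, extract_contact_map, write_contact_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    toy = generate_toy_structure(n_helices=2, helix_length=6, loop_length=4, seed=seed)
    paths["toy_pdb"] = outdir / "toy_hairpins.pdb"
    paths["toy_pdb"].write_text(pdb_text(toy.structure))

    native = extract_contact_map(toy.structure, ContactDefinition())
    paths["native_contacts"] = outdir / "toy_native_contacts.txt"
    write_contact_table(native, paths["native_contacts"])

    cmap = generate_synthetic_contact_map(
        L=80,
        stems=[(5, 40, 8), (20, 70, 8)],
        patches=[((15, 55), 4, 0.8), ((40, 65), 3, 0.8)],
        seed=seed,
    )
    paths["synthetic_map"] = outdir / "synthetic_map.txt"
    write_contact_table(cmap, paths["synthetic_map"])

    table = generate_rmsd_table(60, improve_probability=0.7, seed=seed)
    paths["rmsd_table"] = outdir / "rmsd_table.csv"
    table.to_csv(paths["rmsd_table"])
    return paths
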