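"""Distance-restraint records for folding engines.

A selected contact becomes one flat-bottom distance restraint between the
reference atoms (N1/N9) of its two residues: zero penalty up to the upper
bound, a rising penalty beyond it, and a constant penalty above a cap
distance so one badly violated restraint cannot dominate the energy.  The
exact slope is engine configuration; the writer emits the profile
parameters as header metadata rather than hard-coding energies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, TextIO

from .errors import DomainError, MalformedRecordError
from .structure_io import RnaStructure, reference_atom
from .topology import Selection

__all__ = [
    "Restraint",
    "RestraintSet",
    "build_restraint_set",
    "write_simrna_restraints",
    "read_simrna_restraints",
]

DIALECTS = ("generic",)


@dataclass(frozen=True)
class Restraint:
    """One distance restraint between two residues' reference atoms."""

    chain_a: str
    pos_a: int
    atom_a: str
    chain_b: str
    pos_b: int
    atom_b: str
    lower: float
    upper: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.upper):
            raise DomainError(
                f"restraint bounds must satisfy 0 <= lower < upper, got "
                f"({self.lower}, {self.upper})"
            )


@dataclass(frozen=True)
class RestraintSet:
    """Ordered restraint records plus the flat-bottom penalty profile.

    ``cap_distance`` is where the penalty stops growing (constant cost
    beyond it); it defaults to twice the upper bound.
    """

    records: tuple[Restraint, ...]
    profile: str = "flat-bottom"
    cap_distance: float | None = None

    def __len__(self) -> int:
        return len(self.records)

    def to_json(self) -> str:
        payload = {
            "profile": self.profile,
            "cap_distance": self.cap_distance,
            "records": [asdict(r) for r in self.records],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RestraintSet":
        payload = json.loads(text)
        return cls(
            records=tuple(Restraint(**r) for r in payload["records"]),
            profile=payload.get("profile", "flat-bottom"),
            cap_distance=payload.get("cap_distance"),
        )


def _resolve_context(context: RnaStructure | str):
    """Residue lookup (index -> chain, position, name) from a structure or sequence."""
    if isinstance(context, RnaStructure):
        return [(r.chain, r.position, r.name) for r in context.residues]
    seq = context.strip().upper()
    return [("A", k + 1, letter) for k, letter in enumerate(seq)]


def build_restraint_set(
    selection: Selection,
    context: RnaStructure | str,
    upper: float | None = None,
    lower: float = 0.0,
    weight: float = 1.0,
    cap_distance: float | None = None,
) -> RestraintSet:
    """One restraint per selected contact, atoms via the N1/N9 reference.

    ``context`` supplies residue identities (a structure or a plain
    sequence string); coordinates are not required.  The upper bound
    defaults to the parent map's contact threshold, or 9.5 Å when the map
    carries no geometric definition.
    """
    residues = _resolve_context(context)
    if upper is None:
        definition = selection.parent.definition
        upper = definition.threshold if hasattr(definition, "threshold") else 9.5
    records = []
    for i, j in selection.sorted_contacts():
        for idx in (i, j):
            if not (1 <= idx <= len(residues)):
                raise DomainError(
                    f"contact index {idx} has no residue in the given context "
                    f"(length {len(residues)})"
                )
        ca, pa, na = residues[i - 1]
        cb, pb, nb = residues[j - 1]
        records.append(
            Restraint(
                chain_a=ca, pos_a=pa, atom_a=reference_atom(na),
                chain_b=cb, pos_b=pb, atom_b=reference_atom(nb),
                lower=lower, upper=float(upper), weight=float(weight),
            )
        )
    return RestraintSet(
        records=tuple(records),
        cap_distance=cap_distance if cap_distance is not None else 2.0 * float(upper),
    )


def write_simrna_restraints(
    rset: RestraintSet,
    sink: str | Path | TextIO | None = None,
    dialect: str = "generic",
) -> str:
    """Write restraints as a SimRNA-style whitespace-column text file.

    One line per record: chain, position and atom for each partner, then
    lower bound, upper bound and weight.  Records are sorted by
    (pos_a, pos_b) and the output is byte-deterministic for fixed inputs.
    """
    if dialect not in DIALECTS:
        raise DomainError(f"unknown restraint dialect {dialect!r}")
    lines = [
        f"# dialect={dialect} profile={rset.profile} cap_distance={rset.cap_distance}",
        "# columns: chain_a pos_a atom_a chain_b pos_b atom_b lower upper weight",
    ]
    ordered = sorted(rset.records, key=lambda r: (r.pos_a, r.pos_b, r.chain_a, r.chain_b))
    for r in ordered:
        lines.append(
            f"{r.chain_a} {r.pos_a} {r.atom_a} {r.chain_b} {r.pos_b} {r.atom_b} "
            f"{r.lower:.2f} {r.upper:.2f} {r.weight:.2f}"
        )
    text = "\n".join(lines) + "\n"
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            Path(sink).write_text(text)
    return text


def read_simrna_restraints(source: str | Path | TextIO) -> RestraintSet:
    """Read a restraint file written by :func:`write_simrna_restraints`."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, Path) or ("\n" not in str(source) and Path(str(source)).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    profile, cap = "flat-bottom", None
    records = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line.lstrip("#").split():
                if token.startswith("profile="):
                    profile = token.split("=", 1)[1]
                elif token.startswith("cap_distance="):
                    value = token.split("=", 1)[1]
                    cap = None if value == "None" else float(value)
            continue
        fields = line.split()
        if len(fields) != 9:
            raise MalformedRecordError(f"line {lineno}: expected 9 columns, got {len(fields)}")
        records.append(
            Restraint(
                chain_a=fields[0], pos_a=int(fields[1]), atom_a=fields[2],
                chain_b=fields[3], pos_b=int(fields[4]), atom_b=fields[5],
                lower=float(fields[6]), upper=float(fields[7]), weight=float(fields[8]),
            )
        )
    return RestraintSet(records=tuple(records), profile=profile, cap_distance=cap)
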