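"""Quality metrics: PPV, error rate, the beneficial fraction xi, and a
Kabsch-superposition RMSD utility.

PPV (positive predictive value) is the fraction of predicted contacts that
are native.  For a selection diluted with false contacts at error rate
lambda, PPV = 1 - lambda by construction.  The beneficial fraction
xi = (1/|D|) * sum_d Theta[RMSD(d, free) - RMSD(d, restrained)] is the
fraction of molecules whose restrained folding RMSD is strictly lower
than the unrestrained one (a tie does not count as a benefit).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyMapError,
    InsufficientMatchError,
    UndefinedMetricError,
)
from .structure_io import ContactMap, RnaStructure, reference_atom
from .topology import Selection

__all__ = [
    "RmsdTable",
    "PartitionedXi",
    "ppv",
    "error_rate",
    "beneficial_fraction",
    "partitioned_beneficial_fraction",
    "rmsd",
    "kabsch_superpose",
]

_RMSD_COLUMNS = ["molecule_id", "L", "rmsd_restrained", "rmsd_free"]


@dataclass(frozen=True)
class RmsdTable:
    """Per-molecule RMSD with and without restraints.

    Backed by a DataFrame with columns
    ``molecule_id, L, rmsd_restrained, rmsd_free``; molecule ids are
    unique and RMSD values non-negative.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _RMSD_COLUMNS if c not in df.columns]
        if missing:
            raise DomainError(f"RmsdTable missing columns: {missing}")
        if df["molecule_id"].duplicated().any():
            raise DomainError("molecule ids must be unique")
        if (df["rmsd_restrained"] < 0).any() or (df["rmsd_free"] < 0).any():
            raise DomainError("RMSD values must be >= 0")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, int, float, float]]) -> "RmsdTable":
        return cls(pd.DataFrame(list(rows), columns=_RMSD_COLUMNS))

    @classmethod
    def from_csv(cls, source: str | Path | TextIO) -> "RmsdTable":
        return cls(pd.read_csv(source))

    def to_csv(self, sink: str | Path | TextIO) -> None:
        self.frame.to_csv(sink, index=False)


@dataclass(frozen=True)
class PartitionedXi:
    """Beneficial fraction split at a molecule-size threshold.

    ``xi_small`` / ``xi_large`` are ``None`` when the group is empty
    (undefined, not zero).
    """

    xi_small: float | None
    xi_large: float | None
    n_small: int
    n_large: int
    threshold: int


def _pairs_of(predicted: ContactMap | Selection | Iterable[tuple[int, int]]):
    if isinstance(predicted, Selection):
        return predicted.chosen
    if isinstance(predicted, ContactMap):
        return predicted.contacts
    return frozenset((min(i, j), max(i, j)) for i, j in predicted)


def ppv(
    predicted: ContactMap | Selection | Iterable[tuple[int, int]],
    native: ContactMap,
) -> float:
    """|predicted ∩ native| / |predicted|."""
    pred = _pairs_of(predicted)
    if not pred:
        raise UndefinedMetricError("PPV undefined for an empty prediction")
    if isinstance(predicted, (ContactMap,)) and predicted.L != native.L:
        raise DomainError(f"length mismatch: predicted L={predicted.L}, native L={native.L}")
    if isinstance(predicted, Selection) and predicted.parent.L != native.L:
        raise DomainError("selection parent length differs from native map")
    return len(pred & native.contacts) / len(pred)


def error_rate(selection: Selection) -> float:
    """Fraction of false contacts lambda = |false| / |chosen| = 1 - PPV."""
    if not selection.chosen:
        raise EmptyMapError("error rate undefined for an empty selection")
    return selection.error_rate


def beneficial_fraction(table: RmsdTable) -> float:
    """xi: fraction of molecules strictly improved by restraints."""
    if len(table) == 0:
        raise UndefinedMetricError("beneficial fraction undefined for an empty table")
    df = table.frame
    improved = df["rmsd_restrained"] < df["rmsd_free"]
    return float(improved.mean())


def partitioned_beneficial_fraction(table: RmsdTable, threshold: int) -> PartitionedXi:
    """xi computed separately for molecules with L <= threshold and L > threshold."""
    if threshold < 1:
        raise DomainError("size threshold must be >= 1")
    df = table.frame
    small = df[df["L"] <= threshold]
    large = df[df["L"] > threshold]

    def xi_of(group: pd.DataFrame) -> float | None:
        if len(group) == 0:
            return None
        return float((group["rmsd_restrained"] < group["rmsd_free"]).mean())

    return PartitionedXi(
        xi_small=xi_of(small),
        xi_large=xi_of(large),
        n_small=len(small),
        n_large=len(large),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Kabsch RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(X: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares superposition of Y onto X (Kabsch algorithm).

    Returns (rmsd, rotation R, translation t) such that Y @ R.T + t best
    fits X.  Proper rotations only: a reflection in the SVD solution is
    corrected by flipping the smallest singular direction.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise InsufficientMatchError("superposition needs >= 3 matched 3D points")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    H = Y0.T @ X0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    Yr = Y0 @ R.T
    value = float(np.sqrt(((Yr - X0) ** 2).sum() / X.shape[0]))
    t = xc - yc @ R.T
    return value, R, t


def _matched_coordinates(
    a: RnaStructure, b: RnaStructure, atom_policy: str
) -> tuple[np.ndarray, np.ndarray]:
    def atom_table(s: RnaStructure) -> dict[tuple[str, int, str], np.ndarray]:
        table: dict[tuple[str, int, str], np.ndarray] = {}
        for res in s.residues:
            if atom_policy == "reference":
                ref = reference_atom(res.name)
                names = [ref] if ref in res.atoms else []
            elif atom_policy == "heavy":
                names = list(res.heavy_atoms())
            elif atom_policy == "all":
                names = list(res.atoms)
            else:
                raise DomainError(f"unknown atom policy {atom_policy!r}")
            for name in names:
                table[(res.chain, res.position, name)] = res.atoms[name]
        return table

    ta, tb = atom_table(a), atom_table(b)
    keys = sorted(set(ta) & set(tb))
    if len(keys) < 3:
        raise InsufficientMatchError(
            f"only {len(keys)} atoms matched between {a.id!r} and {b.id!r}"
        )
    return (
        np.asarray([ta[k] for k in keys]),
        np.asarray([tb[k] for k in keys]),
    )


def rmsd(a: RnaStructure, b: RnaStructure, atom_policy: str = "heavy") -> float:
    """RMSD after optimal superposition.

    Atoms are matched by (chain, residue position, atom name).  The
    default policy uses all common heavy atoms; ``"reference"`` restricts
    to the N1/N9 atoms mirroring the contact definition.
    """
    X, Y = _matched_coordinates(a, b, atom_policy)
    value, _, _ = kabsch_superpose(X, Y)
    return value
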