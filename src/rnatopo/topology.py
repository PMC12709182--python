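"""Contact-map topology: Gaussian dispersion score, cluster analysis,
contact-selection schemes, false-contact injection, and the Hopkins
clustering-tendency statistic.

The Gaussian score quantifies how dispersed a set of contacts is on the
contact map.  Each contact i at upper-triangle position r_i receives a
kernel density

    nu_i = sum_{j in C} exp(-|r_i - r_j|^2 / sigma^2)

(the self-term exp(0) = 1 is included, so nu_i >= 1), is down-weighted by
inversion, omega_i = 1 / nu_i, and the score is the total weight

    Omega = sum_i omega_i.

Isolated contacts contribute ~1 each; contacts packed into clusters share
weight, so Omega is small for clustered topologies and approaches |C| for
maximally dispersed ones.  1 <= Omega <= |C| always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import (
    CapacityError,
    DomainError,
    EmptyMapError,
    InsufficientPointsError,
    MalformedRecordError,
    RequestTooLargeError,
)
from .structure_io import ContactMap, WeightedContactMap, _parse_header, _resolve_source

__all__ = [
    "GaussParams",
    "ContactWeights",
    "Selection",
    "ClusterPartition",
    "gauss_weights",
    "gauss_score",
    "normalized_gauss_score",
    "gauss_score_positions",
    "soft_gauss_score",
    "find_clusters",
    "select_clustered",
    "select_random",
    "select_gauss_optimized",
    "inject_false_contacts",
    "hopkins_statistic",
    "default_selection_size",
    "write_selection",
    "read_selection",
]


@dataclass(frozen=True)
class GaussParams:
    """Kernel parameters for the Gaussian score.

    ``sigma2`` is the kernel variance in squared index units; the default
    of 4 places the kernel's reach at a few residues, matching the scale
    of helix runs and tertiary patches on real contact maps.
    """

    sigma2: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise DomainError("sigma2 must be positive")


@dataclass(frozen=True)
class ContactWeights:
    """Per-contact kernel sums nu_i, weights omega_i = 1/nu_i, and Omega."""

    contacts: tuple[tuple[int, int], ...]
    nu: np.ndarray
    omega: np.ndarray

    @property
    def total(self) -> float:
        """The Gaussian score Omega = sum omega_i."""
        return float(self.omega.sum())


@dataclass(frozen=True)
class ClusterPartition:
    """Disjoint contact clusters, sorted by size descending.

    Two contacts are in the same cluster if a path of adjacent contact
    cells connects them; adjacency is pixel adjacency on the map (8- or
    4-connectivity).  Ties in size are broken by the smallest member pair.
    """

    clusters: tuple[frozenset[tuple[int, int]], ...]
    adjacency: int = 8

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


@dataclass(frozen=True)
class Selection:
    """A chosen subset of contacts with scheme metadata and truth labels.

    ``true_set`` holds chosen contacts present in the parent (native) map,
    ``false_set`` the injected non-native pairs; ``error_rate`` is
    lambda = |false_set| / |chosen|.
    """

    parent: ContactMap
    chosen: frozenset[tuple[int, int]]
    scheme: str
    true_set: frozenset[tuple[int, int]]
    false_set: frozenset[tuple[int, int]]
    seed: int | None = None
    sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.true_set | self.false_set != self.chosen:
            raise DomainError("true_set and false_set must partition chosen")
        if self.true_set & self.false_set:
            raise DomainError("true_set and false_set overlap")
        if not self.true_set <= self.parent.contacts:
            raise DomainError("true_set contains non-native pairs")
        if self.false_set & self.parent.contacts:
            raise DomainError("false_set contains native pairs")

    def __len__(self) -> int:
        return len(self.chosen)

    @property
    def error_rate(self) -> float:
        """Fraction of false contacts, lambda."""
        if not self.chosen:
            raise EmptyMapError("error rate undefined for an empty selection")
        return len(self.false_set) / len(self.chosen)

    def sorted_contacts(self) -> list[tuple[int, int]]:
        return sorted(self.chosen)

    def as_contact_map(self) -> ContactMap:
        return ContactMap(
            L=self.parent.L,
            contacts=self.chosen,
            definition="external",
            min_sep=self.parent.min_sep,
        )


def default_selection_size(cmap: ContactMap) -> int:
    """The conventional restraint budget of L/2 contacts (odd L floors)."""
    return cmap.L // 2


# ---------------------------------------------------------------------------
# Gaussian score
# ---------------------------------------------------------------------------

def _positions(contacts: Iterable[tuple[int, int]]) -> np.ndarray:
    return np.asarray(sorted(contacts), dtype=float)


def gauss_score_positions(points: np.ndarray, sigma2: float = 4.0) -> float:
    """Gaussian score of arbitrary real-valued 2D positions.

    Core routine behind :func:`gauss_score`; exposed so the score can be
    evaluated off-lattice (e.g. the two-point closed form
    Omega(d) = 2 / (1 + exp(-d^2/sigma^2))).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise EmptyMapError("Gaussian score undefined for an empty point set")
    sq = cdist(pts, pts, metric="sqeuclidean")
    nu = np.exp(-sq / sigma2).sum(axis=1)
    return float((1.0 / nu).sum())


def gauss_weights(cmap: ContactMap, params: GaussParams = GaussParams()) -> ContactWeights:
    """Per-contact kernel sums and inverse weights (Omega components)."""
    if len(cmap) == 0:
        raise EmptyMapError("Gaussian weights undefined for an empty contact map")
    pts = cmap.positions()
    sq = cdist(pts, pts, metric="sqeuclidean")
    nu = np.exp(-sq / params.sigma2).sum(axis=1)
    return ContactWeights(
        contacts=tuple(cmap.sorted_contacts()), nu=nu, omega=1.0 / nu
    )


def gauss_score(cmap: ContactMap, params: GaussParams = GaussParams()) -> float:
    """The Gaussian score Omega of a contact map."""
    return gauss_weights(cmap, params).total


def normalized_gauss_score(cmap: ContactMap, params: GaussParams = GaussParams()) -> float:
    """Omega / L: the score normalized to the size of the molecule."""
    return gauss_score(cmap, params) / cmap.L


def soft_gauss_score(wmap: WeightedContactMap, params: GaussParams = GaussParams()) -> float:
    """Continuous relaxation of the Gaussian score for real-valued maps.

    Each cell p with weight w_p contributes w_p / nu(p), where
    nu(p) = sum_q w_q exp(-|r_p - r_q|^2 / sigma^2) over all weighted
    cells.  For binary weights this reduces exactly to :func:`gauss_score`;
    it is the form suitable as a loss-function term for map predictors
    that output contact probabilities.
    """
    cells = [(pos, w) for pos, w in sorted(wmap.weights.items()) if w > 0.0]
    if not cells:
        return 0.0
    pts = np.asarray([pos for pos, _ in cells], dtype=float)
    w = np.asarray([wt for _, wt in cells], dtype=float)
    sq = cdist(pts, pts, metric="sqeuclidean")
    nu = (np.exp(-sq / params.sigma2) * w[None, :]).sum(axis=1)
    return float((w / nu).sum())


# ---------------------------------------------------------------------------
# Cluster analysis
# ---------------------------------------------------------------------------

_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = tuple(
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
)


def find_clusters(cmap: ContactMap, adjacency: int = 8) -> ClusterPartition:
    """Connected components of contact cells under pixel adjacency.

    Two contacts belong to one cluster if a path of adjacent contact
    cells connects them.  The default 8-connectivity lets anti-diagonal
    helix runs form single clusters.
    """
    if adjacency not in (4, 8):
        raise DomainError("adjacency must be 4 or 8")
    offsets = _OFFSETS_8 if adjacency == 8 else _OFFSETS_4
    cells = set(cmap.contacts)
    seen: set[tuple[int, int]] = set()
    clusters: list[frozenset[tuple[int, int]]] = []
    for start in sorted(cells):
        if start in seen:
            continue
        stack = [start]
        component: set[tuple[int, int]] = set()
        seen.add(start)
        while stack:
            i, j = stack.pop()
            component.add((i, j))
            for di, dj in offsets:
                nb = (i + di, j + dj)
                if nb in cells and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        clusters.append(frozenset(component))
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return ClusterPartition(clusters=tuple(clusters), adjacency=adjacency)


# ---------------------------------------------------------------------------
# Selection schemes
# ---------------------------------------------------------------------------

def _check_request(cmap: ContactMap, n: int) -> None:
    if len(cmap) == 0:
        raise EmptyMapError("cannot select from an empty contact map")
    if n < 1:
        raise DomainError("selection size n must be >= 1")
    if n > len(cmap):
        raise RequestTooLargeError(
            f"requested {n} contacts but the map has only {len(cmap)}"
        )


def select_clustered(
    cmap: ContactMap,
    n: int | None = None,
    seed: int | None = None,
    adjacency: int = 8,
) -> Selection:
    """Select n contacts cluster by cluster, largest cluster first.

    Contacts are drawn uniformly without replacement from the largest
    cluster until it is exhausted, then from the next cluster in
    descending-size order, emulating the spatially concentrated output of
    convolutional contact predictors.
    """
    if n is None:
        n = default_selection_size(cmap)
    _check_request(cmap, n)
    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, int]] = []
    for cluster in find_clusters(cmap, adjacency).clusters:
        remaining = n - len(chosen)
        if remaining <= 0:
            break
        members = sorted(cluster)
        if len(members) <= remaining:
            chosen.extend(members)
        else:
            idx = rng.choice(len(members), size=remaining, replace=False)
            chosen.extend(members[k] for k in sorted(idx))
    picked = frozenset(chosen)
    return Selection(
        parent=cmap, chosen=picked, scheme="clustered",
        true_set=picked, false_set=frozenset(), seed=seed,
    )


def select_random(
    cmap: ContactMap, n: int | None = None, seed: int | None = None
) -> Selection:
    """Select n contacts uniformly without replacement from the whole map."""
    if n is None:
        n = default_selection_size(cmap)
    _check_request(cmap, n)
    rng = np.random.default_rng(seed)
    members = cmap.sorted_contacts()
    idx = rng.choice(len(members), size=n, replace=False)
    picked = frozenset(members[k] for k in idx)
    return Selection(
        parent=cmap, chosen=picked, scheme="random",
        true_set=picked, false_set=frozenset(), seed=seed,
    )


def select_gauss_optimized(
    cmap: ContactMap,
    n: int | None = None,
    params: GaussParams = GaussParams(),
    seed: int | None = None,
) -> Selection:
    """Select n contacts maximizing the Gaussian score Omega.

    Deterministic greedy construction (seeded from the most distant
    contact pair, then repeatedly adding the contact that maximizes Omega
    of the augmented set) followed by single-swap hill climbing until no
    exchange of one chosen for one unchosen contact increases Omega.  The
    result is locally optimal under single swaps; ties break toward the
    lexicographically smallest contact.  ``seed`` is accepted for
    interface symmetry with the stochastic schemes but unused.
    """
    if n is None:
        n = default_selection_size(cmap)
    _check_request(cmap, n)
    members = cmap.sorted_contacts()
    m = len(members)
    pts = np.asarray(members, dtype=float)
    kernel = np.exp(-cdist(pts, pts, metric="sqeuclidean") / params.sigma2)

    def omega_of(idx: np.ndarray) -> float:
        nu = kernel[np.ix_(idx, idx)].sum(axis=1)
        return float((1.0 / nu).sum())

    if n == 1:
        chosen_idx = np.array([0])
    else:
        sq = cdist(pts, pts, metric="sqeuclidean")
        # argmax over the flattened matrix takes the first (lexicographically
        # smallest) maximizing pair because `members` is sorted.
        a, b = np.unravel_index(int(np.argmax(sq)), sq.shape)
        sel = [min(a, b), max(a, b)]
        in_sel = np.zeros(m, dtype=bool)
        in_sel[sel] = True
        nu = kernel[np.ix_(sel, sel)].sum(axis=1)
        while len(sel) < n:
            cands = np.flatnonzero(~in_sel)
            k_sc = kernel[np.ix_(sel, cands)]              # (s, c)
            nu_aug = nu[:, None] + k_sc                    # existing contacts
            nu_new = 1.0 + k_sc.sum(axis=0)                # the candidate itself
            omega_cand = (1.0 / nu_aug).sum(axis=0) + 1.0 / nu_new
            best = int(np.argmax(omega_cand))              # first max = smallest pair
            c = int(cands[best])
            nu = nu + kernel[sel, c]
            nu = np.append(nu, nu_new[best])
            sel.append(c)
            in_sel[c] = True
        chosen_idx = np.asarray(sel)

    # Single-swap hill climbing (best improvement per pass).
    current = omega_of(chosen_idx)
    improved = True
    while improved:
        improved = False
        in_sel = np.zeros(m, dtype=bool)
        in_sel[chosen_idx] = True
        cands = np.flatnonzero(~in_sel)
        if cands.size == 0:
            break
        nu_full = kernel[np.ix_(chosen_idx, chosen_idx)].sum(axis=1)
        best_gain, best_swap = 1e-12, None
        for pos, a in enumerate(chosen_idx):
            keep = np.delete(chosen_idx, pos)
            nu_keep = np.delete(nu_full, pos) - kernel[keep, a]
            k_kb = kernel[np.ix_(keep, cands)]             # (s-1, c)
            nu_aug = nu_keep[:, None] + k_kb
            nu_new = 1.0 + k_kb.sum(axis=0)
            omega_swap = (1.0 / nu_aug).sum(axis=0) + 1.0 / nu_new
            j = int(np.argmax(omega_swap))
            gain = float(omega_swap[j]) - current
            if gain > best_gain:
                best_gain, best_swap = gain, (pos, int(cands[j]))
        if best_swap is not None:
            pos, b = best_swap
            chosen_idx = np.sort(np.append(np.delete(chosen_idx, pos), b))
            current = omega_of(chosen_idx)
            improved = True

    picked = frozenset(members[k] for k in chosen_idx)
    return Selection(
        parent=cmap, chosen=picked, scheme="gauss",
        true_set=picked, false_set=frozenset(), seed=seed, sigma2=params.sigma2,
    )


# ---------------------------------------------------------------------------
# False-contact injection
# ---------------------------------------------------------------------------

def valid_pair_domain(L: int, min_sep: int) -> int:
    """Number of admissible upper-triangle pairs (j - i >= min_sep)."""
    span = L - min_sep
    return span * (span + 1) // 2 if span > 0 else 0


def inject_false_contacts(
    cmap_native: ContactMap,
    base: Selection,
    lambda_target: float,
    seed: int | None = None,
) -> Selection:
    """Dilute a selection with random non-native pairs at error rate lambda.

    Adds k = round(lambda * |base| / (1 - lambda)) pairs drawn uniformly
    from the admissible index domain minus the native contacts, so the
    resulting fraction of false contacts is k / (|base| + k) ~ lambda and
    the PPV against the native map drops from 1 to 1 - lambda.
    """
    if not (0.0 <= lambda_target < 1.0):
        raise DomainError(f"error rate lambda must lie in [0, 1), got {lambda_target}")
    if lambda_target == 0.0:
        return base
    size = len(base.chosen)
    if size == 0:
        raise EmptyMapError("cannot inject false contacts into an empty selection")
    # round half away from zero, so exact .5 requests are stable
    k = int(math.floor(lambda_target * size / (1.0 - lambda_target) + 0.5))
    if k == 0:
        return base

    L, min_sep = cmap_native.L, cmap_native.min_sep
    excluded = cmap_native.contacts | base.chosen
    candidates = [
        (i, j)
        for i in range(1, L - min_sep + 1)
        for j in range(i + min_sep, L + 1)
        if (i, j) not in excluded
    ]
    if len(candidates) < k:
        raise CapacityError(
            f"need {k} non-native pairs but only {len(candidates)} exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=k, replace=False)
    false_new = frozenset(candidates[i] for i in idx)
    return Selection(
        parent=cmap_native,
        chosen=base.chosen | false_new,
        scheme=base.scheme,
        true_set=base.true_set,
        false_set=base.false_set | false_new,
        seed=seed,
        sigma2=base.sigma2,
    )


# ---------------------------------------------------------------------------
# Hopkins clustering-tendency statistic
# ---------------------------------------------------------------------------

def hopkins_statistic(
    points: ContactMap | Selection | np.ndarray,
    L: int | None = None,
    min_sep: int | None = None,
    reps: int = 100,
    sample_fraction: float = 0.1,
    seed: int | None = None,
) -> float:
    """Hopkins clustering tendency of contact positions, in [0, 1].

    Per repetition, m = max(1, ceil(sample_fraction * N)) uniform probe
    positions are drawn from the admissible index triangle
    {(i, j) : 1 <= i, i + min_sep <= j <= L} and m real points are sampled
    without replacement; with u the probe-to-nearest-data distances and w
    the sampled-data-to-nearest-other-data distances,
    H = sum(u) / (sum(u) + sum(w)).  The mean over ``reps`` repetitions is
    returned.  H ~ 0.5 for spatially uniform points and approaches 1 for
    strongly clustered points.
    """
    if isinstance(points, Selection):
        pts = np.asarray(points.sorted_contacts(), dtype=float)
        L = L if L is not None else points.parent.L
        min_sep = min_sep if min_sep is not None else points.parent.min_sep
    elif isinstance(points, ContactMap):
        pts = points.positions()
        L = L if L is not None else points.L
        min_sep = min_sep if min_sep is not None else points.min_sep
    else:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if L is None:
            raise DomainError("L is required when passing raw point arrays")
        min_sep = 4 if min_sep is None else min_sep

    n_pts = pts.shape[0]
    if n_pts < 2:
        raise InsufficientPointsError("Hopkins statistic needs at least 2 points")
    if not (0.0 < sample_fraction <= 1.0):
        raise DomainError("sample_fraction must lie in (0, 1]")
    if reps < 1:
        raise DomainError("reps must be >= 1")

    m = max(1, math.ceil(sample_fraction * n_pts))
    rng = np.random.default_rng(seed)
    tree = cKDTree(pts)

    def draw_probes(count: int) -> np.ndarray:
        out = np.empty((0, 2))
        while out.shape[0] < count:
            batch = rng.uniform(1.0, float(L), size=(4 * count, 2))
            ok = batch[:, 1] - batch[:, 0] >= min_sep
            out = np.vstack([out, batch[ok]])
        return out[:count]

    values = np.empty(reps)
    for r in range(reps):
        probes = draw_probes(m)
        u, _ = tree.query(probes, k=1)
        sample_idx = rng.choice(n_pts, size=m, replace=False)
        w_all, _ = tree.query(pts[sample_idx], k=2)
        w = w_all[:, 1]  # nearest neighbour excluding self
        values[r] = u.sum() / (u.sum() + w.sum())
    return float(values.mean())


# ---------------------------------------------------------------------------
# Selection serialization (contact-table format + truth column)
# ---------------------------------------------------------------------------

def write_selection(sel: Selection, sink: str | Path | TextIO | None = None) -> str:
    """Serialize a selection as "i j true|false" lines with header metadata."""
    lines = [
        f"# L={sel.parent.L}",
        f"# min_sep={sel.parent.min_sep}",
        f"# scheme={sel.scheme} seed={sel.seed} sigma2={sel.sigma2} "
        f"lambda={sel.error_rate:.6g}",
    ]
    for pair in sel.sorted_contacts():
        label = "true" if pair in sel.true_set else "false"
        lines.append(f"{pair[0]} {pair[1]} {label}")
    text = "\n".join(lines) + "\n"
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            Path(sink).write_text(text)
    return text


def read_selection(
    source: str | Path | TextIO, native: ContactMap | None = None
) -> Selection:
    """Read a selection written by :func:`write_selection`.

    If ``native`` is omitted, the parent map is reconstructed from the
    true-labelled rows (sufficient for error-rate and PPV book-keeping).
    """
    text, _ = _resolve_source(source)
    meta: dict[str, str] = {}
    true_set: set[tuple[int, int]] = set()
    false_set: set[tuple[int, int]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            meta.update(_parse_header([line]))
            continue
        fields = line.split()
        if len(fields) != 3 or fields[2] not in ("true", "false"):
            raise MalformedRecordError(f"line {lineno}: expected 'i j true|false'")
        i, j = int(fields[0]), int(fields[1])
        pair = (min(i, j), max(i, j))
        (true_set if fields[2] == "true" else false_set).add(pair)
    if native is None:
        L = int(meta["L"]) if "L" in meta else max((j for _, j in true_set | false_set), default=1)
        min_sep = int(meta.get("min_sep", 1))
        native = ContactMap(L=L, contacts=frozenset(true_set), min_sep=min_sep)
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    sigma2 = None if meta.get("sigma2") in (None, "None") else float(meta["sigma2"])
    return Selection(
        parent=native,
        chosen=frozenset(true_set | false_set),
        scheme=meta.get("scheme", "external"),
        true_set=frozenset(true_set),
        false_set=frozenset(false_set),
        seed=seed,
        sigma2=sigma2,
    )
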