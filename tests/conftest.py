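import numpy as np
import pytest

import rnatopo as rt


@pytest.fixture(scope="session")
def toy_hairpin():
    """One 5-bp stem with a 4-residue loop (L = 14)."""
    return rt.generate_toy_structure(n_helices=1, helix_length=5, loop_length=4, seed=1)


@pytest.fixture(scope="session")
def two_cluster_map():
    """A map whose 8-connected clusters have sizes 5 and 3."""
    cluster_a = {(1, 10), (1, 11), (2, 10), (2, 11), (3, 11)}
    cluster_b = {(20, 40), (20, 41), (21, 41)}
    return rt.ContactMap(L=50, contacts=frozenset(cluster_a | cluster_b), min_sep=4)


@pytest.fixture(scope="session")
def planted_map():
    """Stems plus tertiary patches: the clustered predictor-style topology."""
    return rt.generate_synthetic_contact_map(
        L=80,
        stems=[(5, 40, 8), (20, 70, 8), (45, 75, 6)],
        patches=[((15, 55), 4, 0.8), ((40, 65), 3, 0.8)],
        seed=0,
    )


def random_contact_map(rng, L=60, min_sep=4, max_contacts=40):
    """Uniformly random admissible contact map (shared test helper)."""
    domain = [
        (i, j) for i in range(1, L - min_sep + 1) for j in range(i + min_sep, L + 1)
    ]
    n = int(rng.integers(1, max_contacts + 1))
    idx = rng.choice(len(domain), size=min(n, len(domain)), replace=False)
    return rt.ContactMap(
        L=L, contacts=frozenset(domain[k] for k in idx), min_sep=min_sep
    )


def reference_omega(pairs, sigma2=4.0):
    """Independent scalar-loop evaluation of the Gaussian score."""
    import math

    pts = sorted(pairs)
    total = 0.0
    for p in pts:
        nu = sum(
            math.exp(-((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2) / sigma2) for q in pts
        )
        total += 1.0 / nu
    return total
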