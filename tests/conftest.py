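"""Shared oracles and fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

AMBIGUOUS = "RYSWKMBDHVN"
ALL_CODES = "ACGT" + AMBIGUOUS


def random_iupac_string(
    rng: np.random.Generator,
    length: int,
    max_ambiguous: int,
    max_product: int = 4096,
) -> str:
    """Random sequence over A/C/G/T with up to ``max_ambiguous`` ambiguity codes.

    The product of per-site expansion sizes is kept at or below
    ``max_product`` (three/four-fold codes are downgraded to dimorphic ones
    when needed) so explicit haplotype enumeration stays brute-forceable.
    """
    from ambiscan.iupac import EXPANSION

    chars = list(rng.choice(list("ACGT"), size=length))
    k = min(int(rng.integers(0, max_ambiguous + 1)), length)
    positions = list(rng.choice(length, size=k, replace=False))
    for pos in positions:
        chars[pos] = str(rng.choice(list(AMBIGUOUS)))
    dimorphic = list("RYSWKM")
    for pos in positions:
        product = int(np.prod([len(EXPANSION[c]) for c in chars]))
        if product <= max_product:
            break
        if len(EXPANSION[chars[pos]]) > 2:
            chars[pos] = str(rng.choice(dimorphic))
    return "".join(chars)


def bruteforce_max_divergence(haplotypes: list[str]) -> float:
    """Oracle: maximum pairwise Hamming p-distance, vectorised over all pairs."""
    if len(haplotypes) < 2:
        return 0.0
    arr = np.frombuffer("".join(haplotypes).encode(), dtype=np.uint8).reshape(
        len(haplotypes), -1
    )
    diff = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return float(diff.max()) / arr.shape[1]


def random_ultrametric(ids: list[str], rng: np.random.Generator, height: float | None = None):
    """Random ultrametric tree as a cophenetic matrix.

    Built top-down: the root joins two random nonempty leaf subsets at a
    height drawn below the parent's, recursively; the cophenetic distance
    between two leaves is twice the height of their lowest common ancestor.
    Continuous draws make all merge heights distinct almost surely, so the
    tree recoverable from the matrix is unique.
    """
    n = len(ids)
    coph = np.zeros((n, n))
    index = {name: i for i, name in enumerate(ids)}

    def build(members: list[str], ceiling: float) -> None:
        if len(members) == 1:
            return
        h = ceiling * (0.5 + 0.45 * rng.random())
        cut = int(rng.integers(1, len(members)))
        order = list(rng.permutation(members))
        left, right = order[:cut], order[cut:]
        for a in left:
            for b in right:
                coph[index[a], index[b]] = coph[index[b], index[a]] = 2 * h
        build(left, h)
        build(right, h)

    build(list(ids), height if height is not None else 1.0)
    return coph


@pytest.fixture(scope="session")
def pul4_fixture():
    from ambiscan import pul4_like

    return pul4_like(seed=20240508 % 2**31)
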