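"""Shared fixtures and brute-force oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from motifspace.design import LibraryDesign, SubPool, build_design, enumerate_design
from motifspace.iupac import IUPAC_TO_BASES, PAIRING_DINUCLEOTIDES
from motifspace.simulate import toy_motif_spec

CODES = sorted(IUPAC_TO_BASES)


def brute_force_union(design: LibraryDesign) -> set[str]:
    """Enumerate a design's sequence set directly (independent of the
    inclusion-exclusion path)."""
    out: set[str] = set()
    for sp in design.subpools:
        for combo in itertools.product(*(sorted(s) for s in sp.sets)):
            out.add("".join(combo))
    return out


def random_design(rng: np.random.Generator, length: int | None = None,
                  max_pools: int = 3) -> LibraryDesign:
    """A random small degenerate design for property tests (<= ~2000 seqs)."""
    L = int(length if length is not None else rng.integers(2, 5))
    n_pools = int(rng.integers(1, max_pools + 1))
    pools = []
    for _ in range(n_pools):
        pools.append("".join(rng.choice(CODES, size=L)))
    w = 1.0 / n_pools
    return LibraryDesign([SubPool(s, w) for s in pools])


def satisfies_pairs(seq: str, pairs) -> bool:
    return all(seq[pc.pos5 - 1] + seq[pc.pos3 - 1] in pc.allowed_pairs for pc in pairs)


@pytest.fixture(scope="session")
def toy_spec():
    return toy_motif_spec()


@pytest.fixture(scope="session")
def toy_design(toy_spec):
    return build_design(toy_spec)


@pytest.fixture(scope="session")
def toy_sequences(toy_design):
    return enumerate_design(toy_design)
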