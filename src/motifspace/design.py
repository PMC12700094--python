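"""Degenerate sub-pool library design and exact combinatorics.

A structured ("secondary structure") library is specified by three kinds of
position constraints: conserved positions carry a single fixed base, variable
unpaired positions carry an allowed base set, and paired positions are
constrained jointly so that the two bases can form a base pair. Because some
pair patterns (e.g. an unconstrained pair that may be AT, TA, CG, GC, GT or
TG) cannot be realised by a single degenerate oligonucleotide, the design is
expanded into several partially degenerate sub-pools that are mixed (by
default equimolarly) to form the final library.

All counting in this module is exact. Unions and intersections of sub-pool
sequence sets are computed by inclusion-exclusion over sub-pool subsets,
where the intersection of product sets factorises position by position.

Positions are 1-based throughout; a pair is written (5' position, 3'
position).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .iupac import (
    ALL_DINUCLEOTIDES,
    BASES,
    PAIRING_DINUCLEOTIDES,
    bases_of,
    code_string_to_sets,
    sets_to_code_string,
    symbol_for,
)

#: inclusion-exclusion over 2^m sub-pool subsets is exact and cheap up to here
MAX_IE_POOLS = 20

#: default cap for explicit enumeration of a design's unique sequences
DEFAULT_ENUMERATION_LIMIT = 1 << 20


class SpecError(ValueError):
    """Raised for invalid or inconsistent motif constraint specifications."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairConstraint:
    """A base-pair constraint between two positions.

    Parameters
    ----------
    pos5, pos3 : int
        1-based positions of the 5' and 3' partner (``pos5 < pos3``).
    allowed_pairs : frozenset of str
        Allowed ordered dinucleotides (5' base then 3' base). Defaults to the
        six pairing combinations AT, TA, CG, GC, GT, TG; custom sets (e.g. a
        noncanonical pair) are permitted.
    """

    pos5: int
    pos3: int
    allowed_pairs: frozenset = field(default=PAIRING_DINUCLEOTIDES)

    def __post_init__(self):
        if not (1 <= self.pos5 < self.pos3):
            raise SpecError(f"require 1 <= pos5 < pos3, got ({self.pos5}, {self.pos3})")
        pairs = frozenset(self.allowed_pairs)
        if not pairs:
            raise SpecError("allowed_pairs must be nonempty")
        if not pairs <= ALL_DINUCLEOTIDES:
            raise SpecError(f"invalid dinucleotides in {sorted(pairs)}")
        object.__setattr__(self, "allowed_pairs", pairs)

    @property
    def positions(self) -> tuple[int, int]:
        return (self.pos5, self.pos3)


@dataclass
class MotifConstraintSpec:
    """Constraints of a motif: conserved, variable unpaired and paired positions.

    Every position ``1..length`` must appear in exactly one of ``conserved``,
    ``variable_unpaired``, or a pair constraint.
    """

    length: int
    conserved: Mapping[int, str]
    variable_unpaired: Mapping[int, frozenset]
    pairs: Sequence[PairConstraint]

    def __post_init__(self):
        self.conserved = {int(p): b.upper() for p, b in self.conserved.items()}
        self.variable_unpaired = {
            int(p): frozenset(b.upper() for b in bs)
            for p, bs in self.variable_unpaired.items()
        }
        self.pairs = list(self.pairs)
        seen: dict[int, str] = {}
        for p, b in self.conserved.items():
            if b not in BASES:
                raise SpecError(f"conserved base at {p} must be a single base, got {b!r}")
            seen[p] = "conserved"
        for p, bs in self.variable_unpaired.items():
            if not bs or not bs <= set(BASES):
                raise SpecError(f"invalid base set at position {p}: {sorted(bs)}")
            if p in seen:
                raise SpecError(f"position {p} assigned twice")
            seen[p] = "variable"
        for pc in self.pairs:
            for p in pc.positions:
                if p in seen:
                    raise SpecError(f"position {p} assigned twice")
                seen[p] = "pair"
        missing = set(range(1, self.length + 1)) - set(seen)
        extra = set(seen) - set(range(1, self.length + 1))
        if missing or extra:
            raise SpecError(
                f"positions must partition 1..{self.length}; "
                f"missing={sorted(missing)}, out_of_range={sorted(extra)}"
            )

    @property
    def variable_positions(self) -> list[int]:
        """All non-conserved positions, sorted."""
        pos = set(self.variable_unpaired)
        for pc in self.pairs:
            pos.update(pc.positions)
        return sorted(pos)

    def pair_groups(self) -> list[tuple[int, ...]]:
        """Position grouping in which each base pair is one unit."""
        grouped = [pc.positions for pc in self.pairs]
        in_pair = {p for g in grouped for p in g}
        singles = [(p,) for p in range(1, self.length + 1) if p not in in_pair]
        return sorted(grouped + singles)


@dataclass(frozen=True)
class SubPool:
    """One partially degenerate oligonucleotide with its mixing fraction."""

    degenerate_sequence: str
    weight: float

    def __post_init__(self):
        if self.weight <= 0:
            raise SpecError("sub-pool weight must be > 0")
        # validates the IUPAC alphabet
        code_string_to_sets(self.degenerate_sequence)

    @property
    def sets(self) -> tuple[frozenset, ...]:
        return code_string_to_sets(self.degenerate_sequence)

    @property
    def size(self) -> int:
        """Number of concrete sequences encoded by this sub-pool."""
        n = 1
        for s in self.sets:
            n *= len(s)
        return n

    def contains(self, sequence: str) -> bool:
        seq = sequence.upper()
        return len(seq) == len(self.degenerate_sequence) and all(
            b in s for b, s in zip(seq, self.sets)
        )


@dataclass
class LibraryDesign:
    """A weighted set of degenerate sub-pools sharing one length.

    ``position_groups``, when present, partitions positions into units (each
    base pair one unit) for grouped distance computations.
    """

    subpools: list[SubPool]
    position_groups: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self):
        if not self.subpools:
            raise SpecError("a design needs at least one sub-pool")
        lengths = {len(sp.degenerate_sequence) for sp in self.subpools}
        if len(lengths) != 1:
            raise SpecError(f"sub-pools have mixed lengths: {sorted(lengths)}")
        total = sum(sp.weight for sp in self.subpools)
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"sub-pool weights must sum to 1, got {total}")

    @property
    def length(self) -> int:
        return len(self.subpools[0].degenerate_sequence)

    def _check_sequence(self, sequence: str) -> str:
        seq = sequence.upper()
        if len(seq) != self.length:
            raise SpecError(f"sequence length {len(seq)} != design length {self.length}")
        if any(b not in BASES for b in seq):
            raise SpecError(f"sequence contains non-ACGT characters: {sequence!r}")
        return seq


# ---------------------------------------------------------------------------
# pair encodings
# ---------------------------------------------------------------------------


def _closure(covered: frozenset) -> tuple[frozenset, frozenset]:
    """Smallest product set X x Z containing a set of dinucleotides."""
    return (frozenset(d[0] for d in covered), frozenset(d[1] for d in covered))


@lru_cache(maxsize=None)
def _expand_cached(allowed: frozenset) -> tuple[tuple[str, str], ...]:
    # Candidate code pairs: every product set X x Z can be shrunk, without
    # losing coverage or gaining off-target dinucleotides, to the closure of
    # the allowed pairs it covers; so only closed products need be searched.
    candidates: dict[tuple[frozenset, frozenset], tuple[frozenset, frozenset]] = {}
    all_sets = [frozenset(c) for r in range(1, 5) for c in itertools.combinations(BASES, r)]
    for x in all_sets:
        for z in all_sets:
            prod = frozenset(a + b for a in x for b in z)
            covered = prod & allowed
            if not covered:
                continue
            cx, cz = _closure(covered)
            cprod = frozenset(a + b for a in cx for b in cz)
            candidates[(cx, cz)] = (cprod & allowed, cprod - allowed)
    cand = sorted(
        candidates.items(), key=lambda kv: (symbol_for(kv[0][0]), symbol_for(kv[0][1]))
    )
    best: tuple | None = None  # (cost, n_codes, symbol tuple)
    for k in range(1, len(allowed) + 1):
        if best is not None and k - 1 >= best[0]:
            break
        for combo in itertools.combinations(cand, k):
            covered = frozenset().union(*(c[1][0] for c in combo))
            if covered != allowed:
                continue
            extras = frozenset().union(*(c[1][1] for c in combo))
            cost = len(extras) + k - 1
            symbols = tuple(
                sorted((symbol_for(c[0][0]), symbol_for(c[0][1])) for c in combo)
            )
            key = (cost, k, symbols)
            if best is None or key < best:
                best = key
    assert best is not None  # (N,N) always covers, so a cover always exists
    return best[2]


def expand_pair_encodings(constraint: PairConstraint) -> list[tuple[str, str]]:
    """Minimal degenerate encodings of a pair constraint.

    Returns the list of ``(code5, code3)`` IUPAC symbol pairs whose products
    jointly contain every allowed dinucleotide, minimising the number of
    non-allowed dinucleotides introduced plus the number of extra
    oligonucleotide syntheses required (each additional code pair multiplies
    the sub-pool count). Ties prefer fewer code pairs, then lexicographic
    order, so output is deterministic.

    For the unconstrained six-pair set the result is exactly
    ``[("R", "Y"), ("Y", "R")]``.
    """
    return list(_expand_cached(constraint.allowed_pairs))


def build_design(spec: MotifConstraintSpec) -> LibraryDesign:
    """Expand a motif constraint spec into its equimolar sub-pool design.

    The sub-pool list is the Cartesian product, over pair constraints, of
    each pair's encoding alternatives; conserved and variable unpaired
    positions are identical across sub-pools.
    """
    template: list[str] = ["?"] * spec.length
    for p, b in spec.conserved.items():
        template[p - 1] = b
    for p, bs in spec.variable_unpaired.items():
        template[p - 1] = symbol_for(bs)
    encodings = [expand_pair_encodings(pc) for pc in spec.pairs]
    pools: list[str] = []
    for combo in itertools.product(*encodings) if encodings else [()]:
        chars = list(template)
        for pc, (c5, c3) in zip(spec.pairs, combo):
            chars[pc.pos5 - 1] = c5
            chars[pc.pos3 - 1] = c3
        pools.append("".join(chars))
    w = 1.0 / len(pools)
    return LibraryDesign(
        subpools=[SubPool(s, w) for s in pools],
        position_groups=tuple(spec.pair_groups()),
    )


# ---------------------------------------------------------------------------
# inclusion-exclusion machinery
# ---------------------------------------------------------------------------


def _ie_terms(pool_sets: Sequence[tuple[frozenset, ...]]):
    """Yield ``(sign, intersected_sets)`` over nonempty sub-pool subsets.

    Terms whose positionwise intersection is empty are skipped.
    """
    m = len(pool_sets)
    if m > MAX_IE_POOLS:
        raise SpecError(
            f"{m} sub-pools exceed the inclusion-exclusion limit ({MAX_IE_POOLS}); "
            "use hashed enumeration on an explicit sequence list instead"
        )
    for r in range(1, m + 1):
        sign = 1 if r % 2 == 1 else -1
        for combo in itertools.combinations(pool_sets, r):
            inter = []
            empty = False
            for sets in zip(*combo):
                s = frozenset.intersection(*sets)
                if not s:
                    empty = True
                    break
                inter.append(s)
            if not empty:
                yield sign, tuple(inter)


def _prod_sizes(sets: Iterable[frozenset]) -> int:
    n = 1
    for s in sets:
        n *= len(s)
    return n


def count_unique(design: LibraryDesign) -> int:
    """Exact number of unique sequences in the union of all sub-pools."""
    return sum(sign * _prod_sizes(sets) for sign, sets in _ie_terms([sp.sets for sp in design.subpools]))


def intersection_count(design_a: LibraryDesign, design_b: LibraryDesign) -> int:
    """Exact size of the intersection of two designs' sequence sets.

    Uses the double inclusion-exclusion identity
    ``|(U A_i) n (U B_j)| = sum_{T,U} (-1)^(|T|+|U|) |n T n n U|``.
    """
    if design_a.length != design_b.length:
        raise SpecError("designs must have equal lengths")
    total = 0
    for sign_a, sets_a in _ie_terms([sp.sets for sp in design_a.subpools]):
        for sign_b, sets_b in _ie_terms([sp.sets for sp in design_b.subpools]):
            term = 1
            for sa, sb in zip(sets_a, sets_b):
                s = sa & sb
                if not s:
                    term = 0
                    break
                term *= len(s)
            total += sign_a * sign_b * term
    return total


def contains(design: LibraryDesign, sequence: str) -> bool:
    """True if any sub-pool encodes the sequence."""
    seq = design._check_sequence(sequence)
    return any(sp.contains(seq) for sp in design.subpools)


def expected_frequency(design: LibraryDesign, sequence: str) -> float:
    """Designed frequency of a sequence in the mixed library.

    Each sub-pool contributes ``weight / size`` if it encodes the sequence;
    frequencies over all unique sequences sum to 1.
    """
    seq = design._check_sequence(sequence)
    return sum(sp.weight / sp.size for sp in design.subpools if sp.contains(seq))


def pair_satisfaction_fraction(
    design: LibraryDesign, pairs: Sequence[PairConstraint]
) -> float:
    """Fraction of unique sequences satisfying every given pair constraint.

    Within a sub-pool (or an intersection of sub-pools) the satisfying count
    factorises as a product over pairs of the number of allowed dinucleotides
    realisable at the two positions, times the product of code sizes at the
    remaining positions; the union is handled by inclusion-exclusion.
    """
    for pc in pairs:
        if pc.pos3 > design.length:
            raise SpecError(f"pair position {pc.pos3} outside design of length {design.length}")
    paired_positions = {p for pc in pairs for p in pc.positions}
    numerator = 0
    for sign, sets in _ie_terms([sp.sets for sp in design.subpools]):
        term = 1
        for pc in pairs:
            s5, s3 = sets[pc.pos5 - 1], sets[pc.pos3 - 1]
            n_ok = sum(1 for a in s5 for b in s3 if a + b in pc.allowed_pairs)
            if n_ok == 0:
                term = 0
                break
            term *= n_ok
        if term:
            for i, s in enumerate(sets, start=1):
                if i not in paired_positions:
                    term *= len(s)
        numerator += sign * term
    return numerator / count_unique(design)


# ---------------------------------------------------------------------------
# censuses and distance distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationCensus:
    """Positions and substitutions a design encodes relative to a reference."""

    substitutions: Mapping[int, tuple[str, ...]]  # position -> non-reference bases

    @property
    def n_positions(self) -> int:
        return len(self.substitutions)

    @property
    def n_substitutions(self) -> int:
        return sum(len(v) for v in self.substitutions.values())


def mutation_census(design: LibraryDesign, reference: str) -> MutationCensus:
    """Census of encoded point substitutions relative to a reference sequence."""
    ref = design._check_sequence(reference)
    subs: dict[int, tuple[str, ...]] = {}
    for i in range(design.length):
        allowed = frozenset().union(*(sp.sets[i] for sp in design.subpools))
        non_ref = sorted(allowed - {ref[i]})
        if non_ref:
            subs[i + 1] = tuple(non_ref)
    return MutationCensus(substitutions=subs)


def allowed_bases_by_position(design: LibraryDesign) -> list[frozenset]:
    """Union of allowed bases at each position across all sub-pools."""
    return [
        frozenset().union(*(sp.sets[i] for sp in design.subpools))
        for i in range(design.length)
    ]


def _normalise_grouping(
    length: int, grouping: Sequence[Sequence[int]] | None
) -> list[tuple[int, ...]]:
    if grouping is None:
        return [(p,) for p in range(1, length + 1)]
    groups = [tuple(sorted(int(p) for p in g)) for g in grouping]
    listed = [p for g in groups for p in g]
    if len(listed) != len(set(listed)):
        raise SpecError("grouping lists a position twice")
    groups += [(p,) for p in range(1, length + 1) if p not in set(listed)]
    return sorted(groups)


def distance_distribution(
    design: LibraryDesign,
    reference: str,
    grouping: Sequence[Sequence[int]] | None = None,
) -> np.ndarray:
    """Exact distribution of (optionally grouped) Hamming distances.

    Returns ``pmf`` with ``pmf[d]`` the fraction of unique library sequences
    at distance ``d`` from the reference. With ``grouping``, each position
    group (e.g. a base pair) counts as a single unit that is either entirely
    matching or mutated. Computed by a polynomial product over units within
    each inclusion-exclusion term.
    """
    ref = design._check_sequence(reference)
    groups = _normalise_grouping(design.length, grouping)
    counts = np.zeros(len(groups) + 1)
    for sign, sets in _ie_terms([sp.sets for sp in design.subpools]):
        poly = np.array([1.0])
        for g in groups:
            size = _prod_sizes(sets[p - 1] for p in g)
            match = 1 if all(ref[p - 1] in sets[p - 1] for p in g) else 0
            poly = np.convolve(poly, np.array([float(match), float(size - match)]))
        counts[: len(poly)] += sign * poly
    total = counts.sum()
    return counts / total


def random_mutagenesis_distance_pmf(n_positions: int, per_position_rate: float) -> np.ndarray:
    """Binomial pmf of mutation counts under uniform per-position mutagenesis.

    Models a library made by randomly mutagenizing a reference at a fixed
    per-position rate (e.g. 21%): the number of mutated positions is
    Binomial(n, rate).
    """
    if not 0.0 <= per_position_rate <= 1.0:
        raise SpecError("per-position rate must be in [0, 1]")
    return stats.binom.pmf(np.arange(n_positions + 1), n_positions, per_position_rate)


# ---------------------------------------------------------------------------
# enumeration (oracle-scale designs and the simulator)
# ---------------------------------------------------------------------------


def enumerate_design(
    design: LibraryDesign, limit: int = DEFAULT_ENUMERATION_LIMIT
) -> list[str]:
    """Sorted list of all unique sequences in the design.

    Intended for small designs (simulation, brute-force oracles); raises if
    the union would exceed ``limit`` sequences.
    """
    if sum(sp.size for sp in design.subpools) > limit:
        raise SpecError(
            f"design too large to enumerate (> {limit} sequences); "
            "raise `limit` explicitly if this is intended"
        )
    seqs: set[str] = set()
    for sp in design.subpools:
        for combo in itertools.product(*(sorted(s) for s in sp.sets)):
            seqs.add("".join(combo))
    return sorted(seqs)
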