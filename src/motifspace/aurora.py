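"""Synthetic reconstruction of an Aurora-like secondary structure library.

The deposited oligonucleotide lists of the Aurora selection study are not
bundled with this package. This module instead provides a SYNTHETIC
reconstruction built from the published encoding grammar: a 46-nt motif with
11 base pairs, of which three are unconstrained (requiring the R-Y / Y-R
split and hence 2^3 = 8 equimolar sub-pools), three are encoded by a single
R-Y degenerate pair, and five are fixed; plus eight degenerate unpaired
positions. The reconstruction is constrained to the library's headline
statistics: 8 sub-pools, 28,311,552 (~2.8e7) unique sequences, a (3/4)^6 =
17.8% fraction able to form all 11 pairs, 35 encoded substitutions, and a
128-sequence intersection with the synthetic random-mutagenesis control
also defined here. It is NOT a transcription of the deposited sub-pools;
per-position coordinates and conserved bases are invented.

Position 34 carries the G/T alternative that distinguishes
substrate-affinity (KM) behaviour in the real motif; both the structured
library and the random control encode it, mirroring the study design.
"""

from __future__ import annotations

from .design import (
    LibraryDesign,
    MotifConstraintSpec,
    PairConstraint,
    SubPool,
    build_design,
)
from .iupac import PAIRING_DINUCLEOTIDES

LENGTH = 46

#: the reference ("most active previously identified") variant, synthetic
REFERENCE = "GGAGGACAGTTCCTGAGAACAGATTCTCAGAGCGGATCGATCCTCC"

_FIXED_PAIRS = {(1, 46): "GC", (2, 45): "GC", (3, 44): "AT", (13, 30): "CG", (14, 29): "TA"}
_RY_PAIRS = [(4, 43), (5, 42), (15, 28)]
_OPEN_PAIRS = [(6, 41), (16, 27), (19, 25)]

#: unpaired degenerate positions (position -> allowed bases)
_VARIABLE_UNPAIRED = {
    8: "AG",      # R
    10: "CT",     # Y
    21: "AT",     # W
    23: "AGT",    # D
    32: "GT",     # K
    33: "CGT",    # B
    34: "GT",     # K  (G/T alternative at the affinity-modulating position)
    37: "ACT",    # H
}


def pairing_constraints() -> list[PairConstraint]:
    """The 11 base pairs, each with the six canonical/wobble pairings allowed.

    Use with :func:`motifspace.design.pair_satisfaction_fraction` to measure
    the fraction of library sequences able to form every pair.
    """
    positions = sorted(list(_FIXED_PAIRS) + _RY_PAIRS + _OPEN_PAIRS)
    return [PairConstraint(p5, p3) for p5, p3 in positions]


def secondary_structure_spec() -> MotifConstraintSpec:
    """Constraint spec of the synthetic secondary structure library."""
    pairs = []
    for (p5, p3), dinuc in sorted(_FIXED_PAIRS.items()):
        pairs.append(PairConstraint(p5, p3, allowed_pairs=frozenset({dinuc})))
    for p5, p3 in _RY_PAIRS:
        # single R-Y synthesis: encodes AT, GC, GT (and the off-target AC)
        pairs.append(PairConstraint(p5, p3, allowed_pairs=frozenset({"AT", "GC", "GT"})))
    for p5, p3 in _OPEN_PAIRS:
        pairs.append(PairConstraint(p5, p3, allowed_pairs=PAIRING_DINUCLEOTIDES))
    variable = {p: frozenset(b) for p, b in _VARIABLE_UNPAIRED.items()}
    taken = {p for pc in pairs for p in pc.positions} | set(variable)
    conserved = {
        p: REFERENCE[p - 1] for p in range(1, LENGTH + 1) if p not in taken
    }
    return MotifConstraintSpec(
        length=LENGTH, conserved=conserved, variable_unpaired=variable, pairs=pairs
    )


def secondary_library() -> LibraryDesign:
    """The eight-sub-pool design expanded from the constraint spec."""
    return build_design(secondary_structure_spec())


#: degenerate pattern of the synthetic random-mutagenesis control: the same
#: number of substitutions (35) and mutated positions (24) as the structured
#: library, at randomly placed positions with randomly chosen identities;
#: 15 mutated positions overlap the structured library's, but the encoded
#: substitutions coincide at only seven of them, giving a 2^7 = 128-sequence
#: intersection between the two libraries.
_CONTROL_PATTERN = {
    4: "K", 5: "S", 6: "R", 7: "H", 8: "M", 9: "B", 10: "K", 11: "D", 12: "V",
    15: "B", 16: "R", 17: "B", 19: "R", 20: "H", 21: "V", 22: "V", 23: "M",
    24: "B", 25: "Y", 26: "H", 27: "Y", 34: "K", 41: "Y", 42: "M",
}


def random_control_design() -> LibraryDesign:
    """Synthetic random-mutagenesis control library (union pattern, one pool)."""
    chars = list(REFERENCE)
    for p, code in _CONTROL_PATTERN.items():
        chars[p - 1] = code
    return LibraryDesign([SubPool("".join(chars), 1.0)])
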