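"""IUPAC degenerate nucleotide codes and base-set arithmetic.

The standard single-letter codes denote nonempty subsets of {A, C, G, T}
(R = A/G, Y = C/T, N = any base, ...). Degenerate oligonucleotide sub-pools
are strings of these codes; set intersection of two codes is the set
intersection of their base sets.
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")

#: symbol -> frozenset of bases (the 15 nonempty subsets)
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

#: the six base-pairing dinucleotides (Watson-Crick plus G-T/T-G wobble),
#: written 5' base then 3' base
PAIRING_DINUCLEOTIDES = frozenset({"AT", "TA", "CG", "GC", "GT", "TG"})

ALL_DINUCLEOTIDES = frozenset(a + b for a in BASES for b in BASES)


def bases_of(symbol: str) -> frozenset[str]:
    """Return the base set of a single IUPAC symbol (case-insensitive)."""
    try:
        return IUPAC_TO_BASES[symbol.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {symbol!r}") from None


def symbol_for(bases) -> str:
    """Return the IUPAC symbol for a nonempty base set."""
    key = frozenset(bases)
    try:
        return BASES_TO_IUPAC[key]
    except KeyError:
        raise ValueError(f"not a valid base set: {sorted(bases)!r}") from None


def code_string_to_sets(code: str) -> tuple[frozenset[str], ...]:
    """Convert a degenerate sequence string to a tuple of base sets."""
    return tuple(bases_of(c) for c in code)


def sets_to_code_string(sets) -> str:
    """Convert a tuple of base sets back to an IUPAC string."""
    return "".join(symbol_for(s) for s in sets)
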