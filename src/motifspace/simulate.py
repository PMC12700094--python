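"""Ground-truth fitness landscapes and simulated single-step selections.

The simulator provides everything the analysis modules need to be tested
without sequencing data: a per-sequence catalytic parameterisation with
additive, base-pairing-bonus and pairwise-epistatic structure on log kcat
plus designated positions that shift log KM only; single-turnover
Michaelis-Menten kinetics under a chosen substrate concentration and
incubation time; and multinomial read sampling of the pre- and
post-selection pools.

Model
-----
For a sequence ``s`` with catalytic parameters ``kcat(s)`` and ``KM(s)``::

    k_obs(s) = kcat(s) * S / (KM(s) + S)
    p_react(s) = 1 - exp(-k_obs(s) * t)

Post-selection read probabilities are proportional to the designed frequency
times ``p_react``; reads are multinomial draws. All randomness is controlled
by explicit integer seeds.

Units: kcat in min^-1, KM and substrate concentration in uM, time in
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import (
    LibraryDesign,
    MotifConstraintSpec,
    PairConstraint,
    enumerate_design,
)
from .iupac import BASES, PAIRING_DINUCLEOTIDES
from .selection import CountTable, SelectionDataset

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SelectionCondition:
    """One selection condition: substrate, time, sequencing depth, seed."""

    substrate_conc: float  # uM
    incubation_time: float  # minutes
    n_reads: int
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.substrate_conc <= 0 or self.incubation_time < 0:
            raise ValueError("substrate concentration and time must be positive")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")


#: study-like default conditions: saturating substrate + short incubation
#: biases toward turnover (kcat), sub-saturating substrate + longer
#: incubation biases toward affinity (KM)
KCAT_CONDITION = SelectionCondition(100.0, 100.0 / 60.0, 1_000_000, seed=0, label="kcat")
KM_CONDITION = SelectionCondition(20.0, 10.0, 1_000_000, seed=0, label="km")


@dataclass
class GroundTruthLandscape:
    """Per-sequence kcat/KM defined by additive + epistatic log contributions.

    The reference sequence has all contributions zero, so its parameters are
    ``base_kcat`` and ``base_km``. Broken base pairs are penalised on
    log kcat (pairing bonus), planting the clustering of active sequences
    around pairing-compatible variants.
    """

    spec: MotifConstraintSpec
    reference: str
    additive: dict = field(default_factory=dict)  # (pos, base) -> dlog kcat
    pair_penalty: dict = field(default_factory=dict)  # (pos5, pos3) -> penalty if unpaired
    epistatic: dict = field(default_factory=dict)  # (i, a, j, b) -> dlog kcat
    km_mod: dict = field(default_factory=dict)  # (pos, base) -> dlog KM
    base_kcat: float = 0.1  # min^-1
    base_km: float = 40.0  # uM

    def log_kcat(self, sequences: list[str]) -> np.ndarray:
        arr = _encode(sequences)
        out = np.zeros(len(sequences))
        for (pos, base), eff in self.additive.items():
            out += eff * (arr[:, pos - 1] == _BASE_INDEX[base])
        for (p5, p3), pen in self.pair_penalty.items():
            paired = _pairing_mask(sequences, p5, p3)
            out -= pen * (~paired)
        for (i, a, j, b), eff in self.epistatic.items():
            out += eff * (
                (arr[:, i - 1] == _BASE_INDEX[a]) & (arr[:, j - 1] == _BASE_INDEX[b])
            )
        return out

    def log_km(self, sequences: list[str]) -> np.ndarray:
        arr = _encode(sequences)
        out = np.zeros(len(sequences))
        for (pos, base), eff in self.km_mod.items():
            out += eff * (arr[:, pos - 1] == _BASE_INDEX[base])
        return out

    def kcat(self, sequences: list[str]) -> np.ndarray:
        return self.base_kcat * np.exp(self.log_kcat(sequences))

    def km(self, sequences: list[str]) -> np.ndarray:
        return self.base_km * np.exp(self.log_km(sequences))

    def k_obs(self, sequences: list[str], substrate_conc: float) -> np.ndarray:
        km = self.km(sequences)
        return self.kcat(sequences) * substrate_conc / (km + substrate_conc)


def _encode(sequences: list[str]) -> np.ndarray:
    flat = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    arr = flat.reshape(len(sequences), -1)
    out = np.zeros_like(arr, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _pairing_mask(sequences: list[str], p5: int, p3: int) -> np.ndarray:
    return np.array(
        [s[p5 - 1] + s[p3 - 1] in PAIRING_DINUCLEOTIDES for s in sequences]
    )


def make_toy_landscape(
    spec: MotifConstraintSpec,
    ruggedness: float = 0.5,
    km_positions: tuple[int, ...] = (),
    seed: int = 0,
    reference: str | None = None,
    additive_sd: float = 1.0,
    pair_penalty: float = 1.5,
    km_shift: float = 2.0,
    n_epistatic: int | None = None,
) -> GroundTruthLandscape:
    """Draw a reproducible ground-truth landscape for a motif spec.

    Additive log-kcat effects are N(0, ``additive_sd``) for every
    non-reference base at each variable position (except ``km_positions``);
    each base pair carries a log-kcat penalty of ``pair_penalty`` when
    broken; ``n_epistatic`` pairwise interaction terms (default: one per
    variable position) are N(0, ``ruggedness``); at each position in
    ``km_positions`` one non-reference base shifts log KM by ``-km_shift``
    (improved affinity) without touching kcat.
    """
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = _default_reference(spec)
    var_positions = spec.variable_positions
    allowed = _allowed_by_position(spec)
    additive: dict = {}
    km_mod: dict = {}
    for pos in var_positions:
        ref_base = reference[pos - 1]
        others = sorted(allowed[pos] - {ref_base})
        if pos in km_positions:
            if not others:
                raise ValueError(f"km position {pos} has no alternative base")
            km_mod[(pos, others[int(rng.integers(len(others)))])] = -km_shift
        else:
            for b in others:
                additive[(pos, b)] = float(rng.normal(0.0, additive_sd))
    pair_pen = {pc.positions: pair_penalty for pc in spec.pairs}
    n_epi = len(var_positions) if n_epistatic is None else n_epistatic
    epi: dict = {}
    kcat_positions = [p for p in var_positions if p not in km_positions]
    if ruggedness > 0 and len(kcat_positions) >= 2:
        while len(epi) < n_epi:
            i, j = sorted(rng.choice(kcat_positions, size=2, replace=False))
            if i == j:
                continue
            a = sorted(allowed[i])[int(rng.integers(len(allowed[i])))]
            b = sorted(allowed[j])[int(rng.integers(len(allowed[j])))]
            # reference combination stays at zero contribution
            if a == reference[i - 1] and b == reference[j - 1]:
                continue
            epi[(int(i), a, int(j), b)] = float(rng.normal(0.0, ruggedness))
    return GroundTruthLandscape(
        spec=spec,
        reference=reference,
        additive=additive,
        pair_penalty=pair_pen,
        epistatic=epi,
        km_mod=km_mod,
    )


def _allowed_by_position(spec: MotifConstraintSpec) -> dict[int, frozenset]:
    allowed = {p: frozenset({b}) for p, b in spec.conserved.items()}
    allowed.update(spec.variable_unpaired)
    for pc in spec.pairs:
        allowed[pc.pos5] = frozenset(d[0] for d in pc.allowed_pairs)
        allowed[pc.pos3] = frozenset(d[1] for d in pc.allowed_pairs)
    return allowed


def _default_reference(spec: MotifConstraintSpec) -> str:
    allowed = _allowed_by_position(spec)
    chars = []
    for p in range(1, spec.length + 1):
        chars.append(sorted(allowed[p])[0])
    for pc in spec.pairs:
        # choose a pairing-compatible reference dinucleotide when possible
        options = sorted(pc.allowed_pairs & PAIRING_DINUCLEOTIDES) or sorted(pc.allowed_pairs)
        chars[pc.pos5 - 1], chars[pc.pos3 - 1] = options[0][0], options[0][1]
    return "".join(chars)


def reaction_probability(
    landscape: GroundTruthLandscape,
    sequences: list[str] | str,
    condition: SelectionCondition,
) -> np.ndarray | float:
    """Fraction of molecules reacted: ``1 - exp(-k_obs * t)``."""
    single = isinstance(sequences, str)
    seqs = [sequences] if single else list(sequences)
    k = landscape.k_obs(seqs, condition.substrate_conc)
    p = 1.0 - np.exp(-k * condition.incubation_time)
    return float(p[0]) if single else p


def simulate_selection(
    design: LibraryDesign,
    landscape: GroundTruthLandscape,
    condition: SelectionCondition,
    enumeration_limit: int = 1 << 18,
) -> tuple[CountTable, CountTable]:
    """Simulate one single-step selection; returns (pre, post) count tables.

    Pre-selection reads are multinomial with probabilities equal to the
    designed sequence frequencies; post-selection probabilities are
    proportional to frequency times reaction probability. Zero-count
    sequences are absent from the returned tables.
    """
    seqs = enumerate_design(design, limit=enumeration_limit)
    freqs = _design_frequencies(design, seqs)
    p = reaction_probability(landscape, seqs, condition)
    rng = np.random.default_rng(condition.seed)
    pre = rng.multinomial(condition.n_reads, freqs)
    post_probs = freqs * p
    post_probs = post_probs / post_probs.sum()
    post = rng.multinomial(condition.n_reads, post_probs)
    return _to_table(seqs, pre), _to_table(seqs, post)


def _design_frequencies(design: LibraryDesign, seqs: list[str]) -> np.ndarray:
    arr = _encode(seqs)
    freqs = np.zeros(len(seqs))
    for sp in design.subpools:
        mask = np.ones(len(seqs), dtype=bool)
        for i, allowed in enumerate(sp.sets):
            ok = np.zeros(len(seqs), dtype=bool)
            for b in allowed:
                ok |= arr[:, i] == _BASE_INDEX[b]
            mask &= ok
        freqs[mask] += sp.weight / sp.size
    return freqs / freqs.sum()


def _to_table(seqs: list[str], counts: np.ndarray) -> CountTable:
    return CountTable({s: int(c) for s, c in zip(seqs, counts) if c > 0})


def make_km_contrast_pair(
    design: LibraryDesign,
    landscape: GroundTruthLandscape,
    km_condition: SelectionCondition | None = None,
    kcat_condition: SelectionCondition | None = None,
) -> tuple[SelectionDataset, SelectionDataset]:
    """Simulate matched KM-biased and kcat-biased selections of one library.

    Returns ``(km_dataset, kcat_dataset)`` built from the post-selection
    counts of each condition.
    """
    km_condition = km_condition or KM_CONDITION
    kcat_condition = kcat_condition or KCAT_CONDITION
    if (km_condition.substrate_conc, km_condition.incubation_time) == (
        kcat_condition.substrate_conc,
        kcat_condition.incubation_time,
    ):
        raise ValueError("the two conditions must differ")
    datasets = []
    for cond in (km_condition, kcat_condition):
        _, post = simulate_selection(design, landscape, cond)
        datasets.append(
            SelectionDataset(
                counts=post,
                substrate_conc=cond.substrate_conc,
                incubation_time=cond.incubation_time,
                label=cond.label,
            )
        )
    return datasets[0], datasets[1]


def toy_motif_spec() -> MotifConstraintSpec:
    """A small 9-nt motif spec (4096 sequences, one sub-pool) for testing.

    One R-Y encoded base pair (1, 9), four fully degenerate loop positions,
    a G/T affinity-style position at 5, one A/T position, and one conserved
    position. Enumerable exhaustively, which makes it suitable for oracle
    comparisons and end-to-end simulated selections.
    """
    return MotifConstraintSpec(
        length=9,
        conserved={8: "C"},
        variable_unpaired={
            2: frozenset("ACGT"),
            3: frozenset("ACGT"),
            4: frozenset("ACGT"),
            5: frozenset("GT"),
            6: frozenset("ACGT"),
            7: frozenset("AT"),
        },
        pairs=[PairConstraint(1, 9, allowed_pairs=frozenset({"AT", "GC", "GT"}))],
    )
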