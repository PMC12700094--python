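"""Epistasis and landscape-smoothness measures from CPM tables.

A mutation's effect in a background is the CPM ratio mutant/background; its
relative effect divides that by the same mutation's effect in a chosen
reference background. Relative effects far from 1 across backgrounds are
the signature of epistasis; their dependence on mutational distance from
the reference measures how smooth the landscape is locally. Pairwise
correlations between positions are quantified by mutual information.

Ratios are never imputed: a record whose background or mutant is unobserved
(or has zero CPM) is reported as missing, and summaries state coverage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iupac import BASES


class EpistasisError(ValueError):
    pass


@dataclass(frozen=True)
class Mutation:
    """A substitution at one position group.

    ``positions`` is a tuple of 1-based positions (a single position, or the
    two positions of a base pair treated as one unit); ``to_state`` gives
    the replacement base(s), one character per position.
    """

    positions: tuple[int, ...]
    to_state: str

    def __post_init__(self):
        if len(self.positions) != len(self.to_state):
            raise EpistasisError("positions and to_state lengths differ")
        if any(b not in BASES for b in self.to_state):
            raise EpistasisError(f"invalid target state {self.to_state!r}")

    def applies_to(self, sequence: str) -> bool:
        """True if the sequence does not already carry the target state."""
        return self.state_of(sequence) != self.to_state

    def state_of(self, sequence: str) -> str:
        return "".join(sequence[p - 1] for p in self.positions)

    def apply(self, sequence: str) -> str:
        chars = list(sequence)
        for p, b in zip(self.positions, self.to_state):
            chars[p - 1] = b
        return "".join(chars)


def point_mutation(position: int, to_base: str) -> Mutation:
    return Mutation(positions=(position,), to_state=to_base)


def mutational_effect(
    cpm_map: Mapping[str, float], background: str, mutation: Mutation
) -> float | None:
    """CPM(background + mutation) / CPM(background), or None if missing.

    Missing members (unobserved or zero CPM) yield ``None`` - never 0 or
    infinity. Raises if the background already carries the target state.
    """
    if not mutation.applies_to(background):
        raise EpistasisError(
            f"mutation {mutation} not applicable: background already "
            f"carries state {mutation.to_state!r}"
        )
    mutant = mutation.apply(background)
    cb = cpm_map.get(background)
    cm = cpm_map.get(mutant)
    if not cb or not cm or cb <= 0 or cm <= 0:
        return None
    return cm / cb


@dataclass
class RelativeEffectSummary:
    """Relative effects of one mutation across observed backgrounds."""

    mutation: Mutation
    reference_effect: float
    backgrounds: list[str]
    relative_effects: np.ndarray
    coverage: float  # fraction of candidate backgrounds with both members observed

    @property
    def log10_range(self) -> float:
        if len(self.relative_effects) == 0:
            return 0.0
        logs = np.log10(self.relative_effects)
        return float(logs.max() - logs.min())

    def quantiles(self, q=(0.05, 0.25, 0.5, 0.75, 0.95)) -> dict[float, float]:
        return {float(qq): float(np.quantile(self.relative_effects, qq)) for qq in q}


def relative_effect_distribution(
    cpm_map: Mapping[str, float],
    mutation: Mutation,
    reference_background: str,
) -> RelativeEffectSummary:
    """Distribution of a mutation's effect relative to the reference background.

    A background is any observed sequence that carries the same state as the
    reference at the mutated position(s) - the mutation then means the same
    substitution everywhere; the relative effect is
    ``effect(background) / effect(reference)``.
    """
    ref_effect = mutational_effect(cpm_map, reference_background, mutation)
    if ref_effect is None:
        raise EpistasisError("reference effect is not computable (missing member)")
    ref_state = mutation.state_of(reference_background)
    backgrounds, rels = [], []
    n_candidates = 0
    for seq in cpm_map:
        if mutation.state_of(seq) != ref_state:
            continue
        n_candidates += 1
        eff = mutational_effect(cpm_map, seq, mutation)
        if eff is None:
            continue
        backgrounds.append(seq)
        rels.append(eff / ref_effect)
    return RelativeEffectSummary(
        mutation=mutation,
        reference_effect=ref_effect,
        backgrounds=backgrounds,
        relative_effects=np.array(rels),
        coverage=(len(rels) / n_candidates) if n_candidates else 0.0,
    )


def grouped_distance(seq_a: str, seq_b: str, groups: Sequence[Sequence[int]]) -> int:
    """Number of position groups at which two sequences differ."""
    return sum(
        any(seq_a[p - 1] != seq_b[p - 1] for p in g) for g in groups
    )


def effect_vs_distance(
    cpm_map: Mapping[str, float],
    reference_background: str,
    mutations: Sequence[Mutation],
    grouping: Sequence[Sequence[int]] | None = None,
    fold_threshold: float = 5.0,
) -> pd.DataFrame:
    """Average mutational-effect deviation per distance from the reference.

    For each mutation and each background distance ``d`` (grouped units:
    each base pair counts as one position), the mutation's mean log10
    relative effect over backgrounds at that distance is computed. Each
    distance bin then reports the mean absolute log10 relative effect over
    mutations and the fraction of mutations whose average effect is within
    ``fold_threshold`` of their effect in the reference.
    """
    L = len(reference_background)
    groups = (
        [tuple(g) for g in grouping]
        if grouping is not None
        else [(p,) for p in range(1, L + 1)]
    )
    log_thresh = math.log10(fold_threshold)
    per_mut_bin: dict[tuple[int, int], list[float]] = {}
    for mi, mut in enumerate(mutations):
        ref_eff = mutational_effect(cpm_map, reference_background, mut) if mut.applies_to(reference_background) else None
        if ref_eff is None:
            warnings.warn(f"mutation {mut} has no reference effect; skipped")
            continue
        ref_state = mut.state_of(reference_background)
        for seq in cpm_map:
            if mut.state_of(seq) != ref_state:
                continue
            eff = mutational_effect(cpm_map, seq, mut)
            if eff is None:
                continue
            d = grouped_distance(seq, reference_background, groups)
            per_mut_bin.setdefault((mi, d), []).append(math.log10(eff / ref_eff))
    # average each mutation within a bin, then aggregate over mutations
    bins: dict[int, list[float]] = {}
    for (mi, d), logs in per_mut_bin.items():
        bins.setdefault(d, []).append(float(np.mean(logs)))
    rows = []
    for d in sorted(bins):
        avg_logs = np.array(bins[d])
        rows.append(
            {
                "distance": d,
                "n_mutations": len(avg_logs),
                "mean_abs_log10_effect": float(np.abs(avg_logs).mean()),
                "fraction_within_fold": float((np.abs(avg_logs) <= log_thresh).mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratified pairwise-distance histograms
# ---------------------------------------------------------------------------


def _seq_matrix(seqs: Sequence[str]) -> np.ndarray:
    flat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return flat.reshape(len(seqs), -1)


def _pairwise_hist(mat: np.ndarray, length: int) -> np.ndarray:
    counts = np.zeros(length + 1)
    for i in range(len(mat) - 1):
        d = (mat[i + 1 :] != mat[i]).sum(axis=1)
        counts += np.bincount(d, minlength=length + 1)
    return counts


def stratified_distance_hist(
    cpm_map: Mapping[str, float],
    strata_cutoffs: Sequence[float] | None = None,
    sample_size: int = 100_000,
    seed: int = 0,
    exact_limit: int = 2000,
) -> dict[str, np.ndarray]:
    """Pairwise Hamming distance histograms per CPM stratum.

    Strata are defined by ascending absolute CPM cutoffs (default: observed
    CPM tertiles), the last stratum being open-ended. Each histogram is
    normalised to 1; all pairs are enumerated when a stratum has at most
    ``exact_limit`` sequences, otherwise ``sample_size`` random pairs are
    drawn with the stated seed. Strata with fewer than two sequences are
    skipped with a warning.
    """
    seqs = sorted(cpm_map)
    values = np.array([cpm_map[s] for s in seqs])
    if strata_cutoffs is None:
        strata_cutoffs = [
            float(np.quantile(values, 1 / 3)),
            float(np.quantile(values, 2 / 3)),
        ]
    if list(strata_cutoffs) != sorted(strata_cutoffs):
        raise EpistasisError("strata cutoffs must be ascending")
    edges = [-math.inf, *strata_cutoffs, math.inf]
    length = len(seqs[0])
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"[{lo:g}, {hi:g})"
        members = [s for s, v in zip(seqs, values) if lo <= v < hi]
        if len(members) < 2:
            warnings.warn(f"stratum {label} has {len(members)} sequences; skipped")
            continue
        mat = _seq_matrix(members)
        if len(members) <= exact_limit:
            counts = _pairwise_hist(mat, length)
        else:
            i = rng.integers(0, len(members), size=sample_size)
            j = rng.integers(0, len(members), size=sample_size)
            keep = i != j
            d = (mat[i[keep]] != mat[j[keep]]).sum(axis=1)
            counts = np.bincount(d, minlength=length + 1).astype(float)
        out[label] = counts / counts.sum()
    return out


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


def positional_mutual_information(
    sequences: Sequence[str],
    position_i: int,
    position_j: int,
    weights: Sequence[float] | None = None,
    miller_madow: bool = True,
) -> float:
    """Mutual information (bits) between the bases at two positions.

    ``MI = sum p(a,b) log2 [p(a,b) / (p(a) p(b))]`` over the weighted joint
    base distribution. Optional per-sequence weights (e.g. CPM) reweight the
    empirical distribution. With ``miller_madow`` the small-sample bias
    correction ``[(K_i - 1) + (K_j - 1) - (K_ij - 1)] / (2 N ln 2)`` is
    added, using the Kish effective sample size for weighted data; the
    corrected value is clamped into ``[0, min(H_i, H_j)]`` so the standard
    MI bounds hold for every input. A constant column gives MI = 0.
    """
    if len(sequences) < 2:
        raise EpistasisError("need at least two sequences")
    if weights is None:
        w = np.ones(len(sequences))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(sequences) or (w < 0).any() or w.sum() == 0:
            raise EpistasisError("weights must be nonnegative with positive sum")
    joint = np.zeros((4, 4))
    idx = {b: k for k, b in enumerate(BASES)}
    for s, ws in zip(sequences, w):
        joint[idx[s[position_i - 1]], idx[s[position_j - 1]]] += ws
    joint /= joint.sum()
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    nz = joint > 0
    mi = float(
        (joint[nz] * np.log2(joint[nz] / np.outer(pi, pj)[nz])).sum()
    )
    hi = float(-(pi[pi > 0] * np.log2(pi[pi > 0])).sum())
    hj = float(-(pj[pj > 0] * np.log2(pj[pj > 0])).sum())
    if miller_madow:
        n_eff = w.sum() ** 2 / (w ** 2).sum()
        k_i, k_j, k_ij = (pi > 0).sum(), (pj > 0).sum(), nz.sum()
        mi += ((k_i - 1) + (k_j - 1) - (k_ij - 1)) / (2 * n_eff * math.log(2))
    return min(max(mi, 0.0), min(hi, hj))


def mutual_information_matrix(
    sequences: Sequence[str],
    weights: Sequence[float] | None = None,
    miller_madow: bool = True,
    cpm_map: Mapping[str, float] | None = None,
    cpm_cutoff: float | None = None,
) -> pd.DataFrame:
    """Symmetric position x position MI matrix (bits).

    If ``cpm_map``/``cpm_cutoff`` are given, only sequences at or above the
    cutoff enter the analysis (the default workflow uses sequences above an
    activity threshold, unweighted).
    """
    seqs = list(sequences)
    if cpm_map is not None and cpm_cutoff is not None:
        keep = [k for k, s in enumerate(seqs) if cpm_map.get(s, 0.0) >= cpm_cutoff]
        seqs = [seqs[k] for k in keep]
        if weights is not None:
            weights = [weights[k] for k in keep]
    if len(seqs) < 2:
        raise EpistasisError("fewer than two sequences after filtering")
    L = len(seqs[0])
    mat = np.zeros((L, L))
    for i in range(1, L + 1):
        for j in range(i + 1, L + 1):
            mat[i - 1, j - 1] = mat[j - 1, i - 1] = positional_mutual_information(
                seqs, i, j, weights=weights, miller_madow=miller_madow
            )
    pos = list(range(1, L + 1))
    return pd.DataFrame(mat, index=pos, columns=pos)
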