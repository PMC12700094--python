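"""End-to-end benchmark computations on synthetic selections.

These functions tie the modules together into the analyses the package is
built for: exact combinatorics of the bundled Aurora-like reconstruction,
CPM fidelity against ground-truth kinetics, recovery of a planted
affinity-modulating position, and the model-guided beam search against its
random-walk control. They are used by the test suite and by the
reproduction script; all randomness derives from explicit integer seeds.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import aurora
from .design import (
    allowed_bases_by_position,
    build_design,
    count_unique,
    enumerate_design,
    intersection_count,
    mutation_census,
    pair_satisfaction_fraction,
)
from .ml import BeamSearchParams, beam_search, fitness_split, precision, train_model
from .selection import CountTable, compute_cpm, scan_position_slopes
from .simulate import (
    SelectionCondition,
    make_km_contrast_pair,
    make_toy_landscape,
    simulate_selection,
    toy_motif_spec,
)

#: the toy study design: one enumerable sub-pool of 4096 sequences
TOY_KM_POSITION = 5


def cpm_worked_example() -> float:
    """CPM of a single read in a 3.8e7-read dataset, rounded to 3 decimals."""
    total = 38_000_000
    table = CountTable({"ACGT": 1, "TTTT": total - 1})
    return round(compute_cpm(table)["ACGT"], 3)


def library_statistics() -> dict:
    """Exact combinatorics of the synthetic Aurora-like reconstruction."""
    lib = aurora.secondary_library()
    control = aurora.random_control_design()
    census = mutation_census(lib, aurora.REFERENCE)
    control_census = mutation_census(control, aurora.REFERENCE)
    return {
        "n_subpools": len(lib.subpools),
        "unique_sequences": count_unique(lib),
        "pair_satisfaction_percent": 100.0
        * pair_satisfaction_fraction(lib, aurora.pairing_constraints()),
        "n_substitutions": census.n_substitutions,
        "n_mutated_positions": census.n_positions,
        "control_n_substitutions": control_census.n_substitutions,
        "control_n_mutated_positions": control_census.n_positions,
        "intersection_with_control": intersection_count(lib, control),
    }


def spearman_cpm_vs_kobs(n_reads: int = 1_000_000, seed: int = 0) -> dict:
    """Rank correlation between post-selection CPM and true k_obs.

    Simulates one kcat-biased selection of the 4096-sequence toy design in
    the single-turnover regime and correlates observed CPM with the
    generative k_obs over observed sequences.
    """
    spec = toy_motif_spec()
    design = build_design(spec)
    seqs = enumerate_design(design)
    landscape = make_toy_landscape(spec, seed=seed)
    cond = SelectionCondition(100.0, 100 / 60, n_reads, seed=seed + 1, label="kcat")
    _, post = simulate_selection(design, landscape, cond)
    cpm = compute_cpm(post)
    k_obs = dict(zip(seqs, landscape.k_obs(seqs, cond.substrate_conc)))
    observed = sorted(cpm)
    rho = stats.spearmanr(
        [cpm[s] for s in observed], [k_obs[s] for s in observed]
    ).statistic
    return {"spearman": float(rho), "n_observed": len(observed), "n_reads": n_reads}


def km_position_recovery(
    n_seeds: int = 50, seed: int = 0, n_reads: int = 200_000, n_boot: int = 200
) -> dict:
    """Fraction of seeds in which the planted KM position tops the slope scan."""
    spec = toy_motif_spec()
    design = build_design(spec)
    hits = 0
    for k in range(n_seeds):
        landscape = make_toy_landscape(spec, km_positions=(TOY_KM_POSITION,), seed=seed + k)
        ds_km, ds_kcat = make_km_contrast_pair(
            design,
            landscape,
            SelectionCondition(20.0, 10.0, n_reads, seed=seed + 1000 + k, label="km"),
            SelectionCondition(100.0, 100 / 60, n_reads, seed=seed + 2000 + k, label="kcat"),
        )
        table = scan_position_slopes(
            ds_kcat, ds_km, spec.variable_positions, n_boot=n_boot, seed=seed + k
        )
        hits += int(table.iloc[0]["position"]) == TOY_KM_POSITION
    return {"recovery_fraction": hits / n_seeds, "n_seeds": n_seeds}


def directed_vs_random_beam(n_seeds: int = 20, seed: int = 0) -> dict:
    """Model-guided beam search against its random-propagation control.

    For each seed: simulate a selection of the toy design, apply the
    fitness split (top-100 test, next-100 validation), train an MLP on the
    merged training+validation data (log10 CPM labels), then run the beam
    search with the canonical parameters (topN_start=5, beam_width=5,
    max_depth=5, top_explored=100) in directed and in random mode and score
    precision against the held-out top 100.
    """
    spec = toy_motif_spec()
    design = build_design(spec)
    alphabet = allowed_bases_by_position(design)
    directed, randomized = [], []
    for k in range(n_seeds):
        landscape = make_toy_landscape(spec, seed=seed + k)
        cond = SelectionCondition(
            100.0, 100 / 60, 1_000_000, seed=seed + 500 + k, label="kcat"
        )
        _, post = simulate_selection(design, landscape, cond)
        cpm = compute_cpm(post)
        train, val, test = fitness_split(cpm, seed=seed + k)
        merged = {**train, **val}
        model = train_model(merged, seed=seed + k, log_labels=True)
        seeds_pool = sorted(merged, key=lambda s: (-merged[s], s))[:5]
        test_top = sorted(test, key=lambda s: (-test[s], s))
        for mode, bucket in (("directed", directed), ("random", randomized)):
            result = beam_search(
                model,
                seeds_pool,
                BeamSearchParams(mode=mode),
                alphabet,
                rng_seed=seed + k,
            )
            bucket.append(precision(result.top, test_top))
    wins = sum(d > r for d, r in zip(directed, randomized))
    ties = sum(d == r for d, r in zip(directed, randomized))
    p_sign = stats.binomtest(wins, n_seeds - ties, alternative="greater").pvalue
    return {
        "directed_mean_precision": float(np.mean(directed)),
        "random_mean_precision": float(np.mean(randomized)),
        "wins": wins,
        "n_seeds": n_seeds,
        "sign_test_p": float(p_sign),
    }


def beam_oracle_agreement(seed: int = 0) -> dict:
    """Beam search with the true-fitness oracle versus exhaustive top-100.

    With saturating beam parameters the search must recover exactly the
    exhaustive top-100 of the enumerable 4096-sequence landscape.
    """
    spec = toy_motif_spec()
    design = build_design(spec)
    seqs = enumerate_design(design)
    landscape = make_toy_landscape(spec, seed=seed)
    k_obs = dict(zip(seqs, landscape.k_obs(seqs, 100.0)))

    class _Oracle:
        def predict(self, ss):
            return np.array([k_obs[s] for s in ss])

    ranked = sorted(seqs, key=lambda s: (-k_obs[s], s))
    params = BeamSearchParams(
        topN_start=5, beam_width=len(seqs), max_depth=32, top_explored=100
    )
    result = beam_search(
        _Oracle(), ranked[:5], params, allowed_bases_by_position(design)
    )
    return {
        "precision_vs_exhaustive": precision(result.top, ranked[:100]),
        "tree_size": len(result.tree),
        "n_landscape": len(seqs),
    }
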