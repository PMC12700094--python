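"""Mutational effects, distance structure, and mutual information."""

import itertools
import math

import numpy as np
import pytest

from motifspace.design import build_design, enumerate_design
from motifspace.epistasis import (
    EpistasisError,
    Mutation,
    effect_vs_distance,
    grouped_distance,
    mutational_effect,
    mutual_information_matrix,
    point_mutation,
    positional_mutual_information,
    relative_effect_distribution,
    stratified_distance_hist,
)
from motifspace.selection import compute_cpm
from motifspace.simulate import (
    SelectionCondition,
    make_toy_landscape,
    simulate_selection,
    toy_motif_spec,
)


def _toy_cpm_16():
    """A complete 16-sequence two-position landscape with exact CPM values."""
    seqs = ["".join(p) + "GG" for p in itertools.product("ACGT", repeat=2)]
    rng = np.random.default_rng(11)
    vals = rng.lognormal(2, 1, size=16)
    return dict(zip(seqs, vals))


class TestMutationalEffect:
    def test_simple_ratios(self):
        cpm = {"AA": 5.0, "CA": 50.0, "GA": 5.0}
        assert mutational_effect(cpm, "AA", point_mutation(1, "C")) == pytest.approx(10.0)
        assert mutational_effect(cpm, "AA", point_mutation(1, "G")) == pytest.approx(1.0)

    def test_missing_member_gives_none(self):
        cpm = {"AA": 5.0}
        assert mutational_effect(cpm, "AA", point_mutation(1, "C")) is None

    def test_inapplicable_mutation_raises(self):
        with pytest.raises(EpistasisError):
            mutational_effect({"AA": 1.0}, "AA", point_mutation(1, "A"))

    def test_all_effects_match_hand_ratios_on_toy_landscape(self):
        cpm = _toy_cpm_16()
        for background in cpm:
            for pos in (1, 2):
                for b in "ACGT":
                    if b == background[pos - 1]:
                        continue
                    mut = point_mutation(pos, b)
                    mutant = background[:pos - 1] + b + background[pos:]
                    assert mutational_effect(cpm, background, mut) == pytest.approx(
                        cpm[mutant] / cpm[background]
                    )

    def test_reciprocity(self):
        """effect(b, m) * effect(b+m, m^-1) = 1 whenever both observed."""
        cpm = _toy_cpm_16()
        for background in cpm:
            for b in "ACGT":
                if b == background[0]:
                    continue
                fwd = mutational_effect(cpm, background, point_mutation(1, b))
                mutant = b + background[1:]
                back = mutational_effect(cpm, mutant, point_mutation(1, background[0]))
                assert fwd * back == pytest.approx(1.0)


class TestRelativeEffects:
    def test_reference_background_gives_relative_effect_one(self):
        cpm = _toy_cpm_16()
        summary = relative_effect_distribution(cpm, point_mutation(1, "C"), "AAGG")
        k = summary.backgrounds.index("AAGG")
        assert summary.relative_effects[k] == pytest.approx(1.0)
        assert summary.coverage == 1.0

    def test_additive_landscape_has_no_epistasis(self):
        """With epistatic terms and pair penalties off, a mutation's CPM
        effect is background-independent in the linear kinetic regime:
        >95% of relative effects are within 2-fold of 1 at 1e6 reads."""
        from motifspace.design import MotifConstraintSpec

        spec = MotifConstraintSpec(
            length=5,
            conserved={5: "C"},
            variable_unpaired={
                1: frozenset("ACGT"),
                2: frozenset("ACGT"),
                3: frozenset("AT"),
                4: frozenset("GT"),
            },
            pairs=[],
        )
        design = build_design(spec)
        landscape = make_toy_landscape(spec, ruggedness=0.0, pair_penalty=0.0, seed=6)
        cond = SelectionCondition(5.0, 0.05, 1_000_000, seed=60)  # linear regime
        _, post = simulate_selection(design, landscape, cond)
        cpm = compute_cpm(post)
        fracs = []
        for pos, base in [(1, "C"), (2, "T"), (4, "T")]:
            summary = relative_effect_distribution(
                cpm, point_mutation(pos, base), landscape.reference
            )
            logs = np.abs(np.log10(summary.relative_effects))
            fracs.append((logs <= math.log10(2.0)).mean())
        assert np.mean(fracs) > 0.95

    def test_log_range_grows_with_planted_interaction_strength(self, toy_spec, toy_design):
        ranges = []
        for rug in (0.0, 2.0):
            landscape = make_toy_landscape(
                toy_spec, ruggedness=rug, pair_penalty=0.0, seed=7, n_epistatic=12
            )
            cond = SelectionCondition(5.0, 0.5, 2_000_000, seed=70)
            _, post = simulate_selection(toy_design, landscape, cond)
            cpm = compute_cpm(post)
            summary = relative_effect_distribution(
                cpm, point_mutation(3, "C"), landscape.reference
            )
            ranges.append(summary.log10_range)
        assert ranges[1] > ranges[0]


class TestEffectVsDistance:
    def test_distance_zero_bin_is_exactly_one(self):
        cpm = _toy_cpm_16()
        table = effect_vs_distance(cpm, "AAGG", [point_mutation(1, "C")])
        row0 = table[table["distance"] == 0].iloc[0]
        assert row0["mean_abs_log10_effect"] == pytest.approx(0.0)
        assert row0["fraction_within_fold"] == 1.0

    def test_bins_match_brute_force(self):
        cpm = _toy_cpm_16()
        mut = point_mutation(2, "T")
        ref = "AAGG"
        table = effect_vs_distance(cpm, ref, [mut])
        ref_eff = cpm["ATGG"] / cpm["AAGG"]
        expected: dict[int, list[float]] = {}
        for b in cpm:
            if b[1] != "A":  # backgrounds carry the reference state at pos 2
                continue
            mutant = b[0] + "T" + b[2:]
            d = sum(x != y for x, y in zip(b, ref))
            expected.setdefault(d, []).append(
                math.log10((cpm[mutant] / cpm[b]) / ref_eff)
            )
        for d, logs in expected.items():
            row = table[table["distance"] == d].iloc[0]
            assert row["mean_abs_log10_effect"] == pytest.approx(abs(np.mean(logs)))

    def test_grouped_distance_treats_pairs_as_units(self):
        assert grouped_distance("GC", "AT", [(1, 2)]) == 1
        assert grouped_distance("GC", "GC", [(1, 2)]) == 0


class TestStratifiedDistances:
    def test_single_stratum_of_near_identical_sequences(self):
        out = stratified_distance_hist({"AATT": 1.0, "AATA": 1.5}, strata_cutoffs=[])
        assert out["[-inf, inf)"][1] == pytest.approx(1.0)

    def test_understaffed_stratum_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = stratified_distance_hist(
                {"AAAA": 5.0, "AAAC": 500.0, "AACC": 600.0}, strata_cutoffs=[100.0]
            )
        assert list(out) == ["[100, inf)"]

    def test_two_sequences_at_distance_three(self):
        out = stratified_distance_hist({"AAAA": 1.0, "ACCC": 2.0}, strata_cutoffs=[])
        assert out["[-inf, inf)"][3] == pytest.approx(1.0)

    def test_subsampling_converges_to_exact_histogram(self):
        rng = np.random.default_rng(8)
        seqs = {"".join(rng.choice(list("ACGT"), size=6)): 1.0 for _ in range(300)}
        exact = stratified_distance_hist(seqs, strata_cutoffs=[], exact_limit=10_000)
        approx = stratified_distance_hist(
            seqs, strata_cutoffs=[], exact_limit=10, sample_size=200_000, seed=1
        )
        tv = 0.5 * np.abs(exact["[-inf, inf)"] - approx["[-inf, inf)"]).sum()
        assert tv < 0.05

    def test_active_stratum_is_clustered_on_pairing_landscape(self, toy_spec, toy_design):
        """Sequences in the top CPM stratum (pairing bonus intact) are closer
        to each other on average than the whole library is."""
        landscape = make_toy_landscape(toy_spec, seed=9, pair_penalty=3.0)
        cond = SelectionCondition(100.0, 100 / 60, 1_000_000, seed=90)
        _, post = simulate_selection(toy_design, landscape, cond)
        cpm = compute_cpm(post)
        hists = stratified_distance_hist(cpm, exact_limit=5000, seed=2)
        labels = list(hists)
        dist = np.arange(len(hists[labels[0]]))
        mean_low = (hists[labels[0]] * dist).sum()
        mean_high = (hists[labels[-1]] * dist).sum()
        assert mean_high < mean_low


class TestMutualInformation:
    def test_perfectly_covarying_equiprobable_columns_give_one_bit(self):
        seqs = ["AT", "TA"] * 50
        assert positional_mutual_information(seqs, 1, 2) == pytest.approx(1.0)

    def test_independent_uniform_columns_approach_zero(self):
        rng = np.random.default_rng(10)
        seqs = ["".join(rng.choice(list("ACGT"), size=2)) for _ in range(20_000)]
        mi = positional_mutual_information(seqs, 1, 2)
        assert mi < 0.005

    def test_constant_column_gives_zero(self):
        seqs = ["AC", "AG", "AT", "AA"]
        assert positional_mutual_information(seqs, 1, 2) == 0.0

    def test_weighted_equals_duplication(self):
        seqs = ["AT", "TA", "AA"]
        weights = [3, 2, 1]
        dup = ["AT"] * 3 + ["TA"] * 2 + ["AA"]
        a = positional_mutual_information(seqs, 1, 2, weights=weights, miller_madow=False)
        b = positional_mutual_information(dup, 1, 2, miller_madow=False)
        assert a == pytest.approx(b)

    def test_symmetry_nonnegativity_and_entropy_bound(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(2, 60))
            seqs = ["".join(rng.choice(list("ACGT"), size=3)) for _ in range(n)]
            for mm in (False, True):
                mij = positional_mutual_information(seqs, 1, 3, miller_madow=mm)
                mji = positional_mutual_information(seqs, 3, 1, miller_madow=mm)
                assert mij == pytest.approx(mji)
                assert mij >= 0.0
                for pos in (1, 3):
                    counts = np.array(
                        [sum(s[pos - 1] == b for s in seqs) for b in "ACGT"], float
                    )
                    p = counts[counts > 0] / counts.sum()
                    h = -(p * np.log2(p)).sum()
                    assert mij <= h + 1e-12

    def test_matrix_is_symmetric_and_cutoff_filters(self):
        cpm = {"AAT": 100.0, "TTA": 90.0, "ATA": 0.5}
        mat = mutual_information_matrix(sorted(cpm), cpm_map=cpm, cpm_cutoff=10.0)
        assert np.allclose(mat.values, mat.values.T)
        assert mat.shape == (3, 3)
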