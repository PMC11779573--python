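"""The Cov_GE estimator chain, its invariances, and resampling inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from countergrad.core_data import ReplicateSummary
from countergrad.covge import (
    DEFAULT_PAIRING,
    DegeneratePhenotypesError,
    bootstrap_ci,
    covge_estimate,
    covge_from_summaries,
    marginal_means,
    permutation_test,
    run_covge_per_species,
    standardize_phenotypes,
)
from tests.conftest import make_summary


def oracle_covge(values_by_group, pairing=None, ddof=0):
    """Direct transcription of the estimation recipe for
    single-observation-per-group inputs: center each phenotype on the grand
    mean, divide by the SD of group means, average genotype and environment
    margins, and sum the native-pair products over n - 1."""
    pairing = pairing or DEFAULT_PAIRING
    groups = list(values_by_group)
    vals = np.array([values_by_group[g] for g in groups])
    std = (vals - vals.mean()) / vals.std(ddof=ddof)
    gens = sorted({g for g, _ in groups})
    envs = sorted({e for _, e in groups})
    G = {g: np.mean([std[i] for i, (gg, _) in enumerate(groups) if gg == g]) for g in gens}
    E = {e: np.mean([std[i] for i, (_, ee) in enumerate(groups) if ee == e]) for e in envs}
    cov = sum(G[g] * E[pairing[g]] for g in gens) / (len(gens) - 1)
    return float(np.clip(cov, -1, 1))


def summaries_from_props(props, n=1000, species="saxatilis"):
    """One replicate per (population, treatment) group at the stated proportion."""
    return [
        make_summary(pop, tr, n, int(round(p * n)), species=species)
        for (pop, tr), p in props.items()
    ]


class TestStandardization:
    def test_hand_worked_values(self, four_group_summaries):
        std = standardize_phenotypes(four_group_summaries)
        by_key = dict(zip(std.group_keys, std.values))
        assert by_key[("N", "cold")] == pytest.approx(0.0, abs=1e-12)
        assert by_key[("N", "heat")] == pytest.approx(np.sqrt(2), abs=1e-4)
        assert by_key[("S", "cold")] == pytest.approx(-np.sqrt(2), abs=1e-4)
        assert std.sd_group == pytest.approx(np.sqrt(0.08), abs=1e-12)
        assert std.values.mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_phenotypes_degenerate(self):
        data = [make_summary(pop, tr, 10, 5) for pop in "NS" for tr in ("heat", "cold")]
        with pytest.raises(DegeneratePhenotypesError):
            standardize_phenotypes(data)

    def test_standardized_group_means_have_unit_sd(self, four_group_summaries):
        std = standardize_phenotypes(four_group_summaries)
        gm = {}
        for v, k in zip(std.values, std.group_keys):
            gm.setdefault(k, []).append(v)
        means = np.array([np.mean(v) for v in gm.values()])
        assert means.std(ddof=0) == pytest.approx(1.0, abs=1e-12)


class TestMarginalMeans:
    def test_hand_worked_margins(self, four_group_summaries):
        mm = marginal_means(standardize_phenotypes(four_group_summaries))
        assert mm.genotype_means["N"] == pytest.approx(np.sqrt(2) / 2, abs=1e-4)
        assert mm.genotype_means["S"] == pytest.approx(-np.sqrt(2) / 2, abs=1e-4)
        assert mm.environment_means["cold"] == pytest.approx(-np.sqrt(2) / 2, abs=1e-4)
        assert mm.environment_means["heat"] == pytest.approx(np.sqrt(2) / 2, abs=1e-4)

    def test_pure_genotype_effect_zeroes_environment_margins(self):
        data = summaries_from_props(
            {("N", "heat"): 1.0, ("N", "cold"): 1.0, ("S", "heat"): 0.0, ("S", "cold"): 0.0}
        )
        mm = marginal_means(standardize_phenotypes(data))
        assert mm.environment_means["heat"] == pytest.approx(0.0, abs=1e-12)
        assert mm.environment_means["cold"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_cell_rejected(self):
        data = [
            make_summary("N", "heat", 10, 9),
            make_summary("N", "cold", 10, 4),
            make_summary("S", "heat", 10, 6),
        ]
        with pytest.raises(ValueError, match="unobserved"):
            marginal_means(standardize_phenotypes(data))

    def test_balanced_margins_equal_simple_averages(self, rng):
        data = []
        for pop in "NS":
            for tr in ("heat", "cold"):
                for _ in range(3):
                    a = int(rng.integers(1, 10))
                    data.append(make_summary(pop, tr, 10, a))
        std = standardize_phenotypes(data)
        mm = marginal_means(std)
        cell = {}
        for v, k in zip(std.values, std.group_keys):
            cell.setdefault(k, []).append(v)
        for pop in "NS":
            simple = np.mean([np.mean(cell[(pop, tr)]) for tr in ("heat", "cold")])
            assert mm.genotype_means[pop] == pytest.approx(simple, abs=1e-12)


class TestEstimate:
    def test_perfect_countergradient_attains_minus_one(self, four_group_summaries):
        assert covge_from_summaries(four_group_summaries) == pytest.approx(-1.0, abs=1e-3)

    def test_mirrored_data_attains_plus_one(self):
        data = summaries_from_props(
            {("N", "heat"): 0.5, ("N", "cold"): 0.9, ("S", "heat"): 0.1, ("S", "cold"): 0.5}
        )
        assert covge_from_summaries(data) == pytest.approx(1.0, abs=1e-12)

    def test_pure_single_factor_effects_give_zero(self):
        pure_g = summaries_from_props(
            {("N", "heat"): 0.9, ("N", "cold"): 0.9, ("S", "heat"): 0.3, ("S", "cold"): 0.3}
        )
        pure_e = summaries_from_props(
            {("N", "heat"): 0.8, ("N", "cold"): 0.2, ("S", "heat"): 0.8, ("S", "cold"): 0.2}
        )
        assert covge_from_summaries(pure_g) == pytest.approx(0.0, abs=1e-12)
        assert covge_from_summaries(pure_e) == pytest.approx(0.0, abs=1e-12)

    def test_pairing_swap_negates_estimate(self, four_group_summaries):
        est = covge_from_summaries(four_group_summaries)
        swapped = covge_from_summaries(
            four_group_summaries, pairing={"N": "heat", "S": "cold"}
        )
        assert swapped == pytest.approx(-est, abs=1e-12)

    def test_unknown_pairing_rejected(self, four_group_summaries):
        std = standardize_phenotypes(four_group_summaries)
        mm = marginal_means(std)
        with pytest.raises(ValueError, match="pairing"):
            covge_estimate(mm, pairing={"N": "cold"})

    def test_sample_sd_convention_bounds_additive_case_at_075(self, four_group_summaries):
        est = covge_from_summaries(four_group_summaries, sd_convention="sample")
        assert est == pytest.approx(-0.75, abs=1e-3)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=4, max_size=4, unique=True
        )
    )
    def test_oracle_agreement_and_boundedness(self, props):
        keys = [("N", "heat"), ("N", "cold"), ("S", "heat"), ("S", "cold")]
        data = [
            make_summary(pop, tr, 1000, int(round(p * 1000)))
            for (pop, tr), p in zip(keys, props)
        ]
        vals = {k: d.prop_surviving for k, d in zip(keys, data)}
        if np.std(list(vals.values())) == 0:
            return
        est = covge_from_summaries(data)
        assert est == pytest.approx(oracle_covge(vals), abs=1e-12)
        assert -1.0 <= est <= 1.0

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=0.05, max_value=20),
        st.floats(min_value=-50, max_value=50),
    )
    def test_affine_invariance(self, scale, shift):
        # Cov_GE unchanged by positive-slope affine maps of the raw phenotype;
        # exercised through the oracle on arbitrary (non-proportion) values
        vals = {("N", "heat"): 0.9, ("N", "cold"): 0.4, ("S", "heat"): 0.5, ("S", "cold"): 0.15}
        mapped = {k: scale * v + shift for k, v in vals.items()}
        assert oracle_covge(mapped) == pytest.approx(oracle_covge(vals), abs=1e-9)

    def test_location_invariance_of_standardization(self, four_group_summaries):
        # adding a constant to all phenotypes leaves standardized values
        # unchanged (checked via the oracle: proportions cannot be shifted)
        vals = {("N", "heat"): 0.9, ("N", "cold"): 0.5, ("S", "heat"): 0.5, ("S", "cold"): 0.1}
        shifted = {k: v + 3.7 for k, v in vals.items()}
        assert oracle_covge(shifted) == pytest.approx(oracle_covge(vals), abs=1e-12)


class TestBootstrap:
    def test_internally_constant_groups_give_zero_width_ci(self):
        data = summaries_from_props(
            {("N", "heat"): 1.0, ("N", "cold"): 0.0, ("S", "heat"): 0.0, ("S", "cold"): 1.0},
            n=20,
        )
        est = covge_from_summaries(data)
        lo, hi = bootstrap_ci(data, n_boot=99, seed=1)
        assert lo == pytest.approx(est, abs=1e-12)
        assert hi == pytest.approx(est, abs=1e-12)

    def test_seed_determinism(self, four_group_summaries):
        a = bootstrap_ci(four_group_summaries, n_boot=99, seed=42)
        b = bootstrap_ci(four_group_summaries, n_boot=99, seed=42)
        c = bootstrap_ci(four_group_summaries, n_boot=99, seed=43)
        assert a == b
        assert a != c

    def test_replicate_unit_option(self, rng):
        data = []
        for pop in "NS":
            for tr in ("heat", "cold"):
                base = {"N": 0.8, "S": 0.3}[pop] + (0.1 if tr == "heat" else -0.1)
                for _ in range(6):
                    a = rng.binomial(10, base)
                    data.append(make_summary(pop, tr, 10, int(a)))
        lo, hi = bootstrap_ci(data, n_boot=99, seed=7, unit="replicate")
        assert -1 <= lo <= hi <= 1

    def test_ci_brackets_estimate_for_well_behaved_data(self, rng):
        data = []
        for pop in "NS":
            for tr in ("heat", "cold"):
                p = {("N", "heat"): 0.85, ("N", "cold"): 0.55, ("S", "heat"): 0.5, ("S", "cold"): 0.2}[(pop, tr)]
                for _ in range(5):
                    data.append(make_summary(pop, tr, 10, int(rng.binomial(10, p))))
        est = covge_from_summaries(data)
        lo, hi = bootstrap_ci(data, n_boot=399, seed=3)
        assert lo <= est <= hi


class TestPermutation:
    def test_p_at_least_add_one_bound(self, four_group_summaries):
        p = permutation_test(four_group_summaries, n_perm=99, seed=0)
        assert p >= 1 / 100

    def test_degenerate_input_gives_p_one(self):
        data = summaries_from_props(
            {("N", "heat"): 0.5, ("N", "cold"): 0.5, ("S", "heat"): 0.5, ("S", "cold"): 0.5}
        )
        assert permutation_test(data, n_perm=99, seed=0) == 1.0

    def test_strong_signal_gives_small_p(self, rng):
        # the re-standardized statistic is scale-free, so its permutation
        # null stays broad: even a near-perfect additive pattern bottoms out
        # around p ~ 0.1 (the chance a random 2x2 pattern looks additive);
        # assert the p lands near that floor, far below the null median
        data = []
        for pop in "NS":
            for tr in ("heat", "cold"):
                p = {("N", "heat"): 0.95, ("N", "cold"): 0.6, ("S", "heat"): 0.4, ("S", "cold"): 0.05}[(pop, tr)]
                for _ in range(12):
                    data.append(make_summary(pop, tr, 20, int(rng.binomial(20, p))))
        assert permutation_test(data, n_perm=399, seed=5) < 0.15


class TestPerSpecies:
    def test_three_species_give_three_results(self):
        data = []
        idx = 0
        for sp in ("littorea", "obtusata", "saxatilis"):
            for pop in "NS":
                for tr in ("heat", "cold"):
                    p = 0.8 if (pop == "N") != (tr == "heat") else 0.4
                    for b in "AB":
                        data.append(
                            make_summary(pop, tr, 10, int(round(p * 10)), species=sp, block=b)
                        )
                    idx += 1
        results = run_covge_per_species(data, n_boot=49, n_perm=49, seed=1)
        assert [r.species for r in results] == ["littorea", "obtusata", "saxatilis"]
        for r in results:
            assert -1 <= r.ci_low <= r.ci_high <= 1
            assert r.pairing == DEFAULT_PAIRING

    def test_species_missing_environment_skipped(self, caplog):
        data = [
            make_summary("N", "heat", 10, 8, species="littorea"),
            make_summary("S", "heat", 10, 4, species="littorea"),
        ]
        results = run_covge_per_species(data, n_boot=9, n_perm=9, seed=1)
        assert results == []

    def test_countergradient_preset_detected(self):
        from countergrad.core_data import aggregate_to_replicates
        from countergrad.synth import preset_scenarios, simulate_dataset

        cfg = preset_scenarios("countergradient", seed=6, n_per_replicate=60)
        summ = aggregate_to_replicates(simulate_dataset(cfg))
        results = run_covge_per_species(summ, n_boot=199, n_perm=199, seed=11)
        assert len(results) == 3
        for r in results:
            assert r.estimate < 0
        # significance in practice rests on the bootstrap CI excluding zero
        assert sum(r.significant_by_ci for r in results) >= 2
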