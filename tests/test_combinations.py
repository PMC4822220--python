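"""Chimera-mixture emissions and ML combination-set inference."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paracopy import (
    ChimeraModel,
    SimulationConfig,
    combination_proportion_ci,
    combine_datasets,
    demo_paralogue_set,
    emission_distribution,
    infer_combination_set,
    set_log_likelihood,
    simulate_counts,
)
from paracopy.observations import CombinationCounts


def oracle_emission(copies, c):
    """Direct enumeration over parent pairs and breakpoints (uniform gaps)."""
    k = len(copies)
    v = len(copies[0])
    probs = {}
    for s in copies:
        probs[s] = probs.get(s, 0.0) + (1 - c) / k
    if c > 0:
        for left, right in itertools.product(copies, repeat=2):
            for b in range(1, v):
                s = left[:b] + right[b:]
                probs[s] = probs.get(s, 0.0) + c / (k * k * (v - 1))
    return probs


class TestEmission:
    def test_degenerate_single_combination(self):
        probs = emission_distribution(["AAA"] * 7, c=0.0)
        assert probs == {"AAA": 1.0}

    def test_hand_enumerated_two_copy_case(self):
        # k=2, V=2, copies {AG, CT}, c=0.1: four ordered parent pairs, one
        # breakpoint; chimeras of identical parents re-emit the parent
        probs = emission_distribution(["AG", "CT"], c=0.1)
        assert probs["AT"] == pytest.approx(0.025, abs=1e-15)
        assert probs["CG"] == pytest.approx(0.025, abs=1e-15)
        assert probs["AG"] == pytest.approx(0.475, abs=1e-15)
        assert probs["CT"] == pytest.approx(0.475, abs=1e-15)

    def test_chimera_needs_two_sites(self):
        with pytest.raises(ValueError, match="V = 1"):
            emission_distribution(["A", "G"], c=0.1)
        assert emission_distribution(["A", "G"], c=0.0) == {"A": 0.5, "G": 0.5}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        k=st.integers(2, 8),
        v=st.integers(2, 5),
        c=st.floats(0, 0.99),
        seed=st.integers(0, 10**6),
    )
    def test_normalization_fuzzed(self, k, v, c, seed):
        rng = np.random.default_rng(seed)
        copies = ["".join(rng.choice(["A", "G"], size=v)) for _ in range(k)]
        probs = emission_distribution(copies, c=c)
        assert math.isclose(sum(probs.values()), 1.0, abs_tol=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(2, 7))
            v = int(rng.integers(2, 5))
            copies = ["".join(rng.choice(["A", "C"], size=v)) for _ in range(k)]
            c = float(rng.uniform(0, 0.3))
            got = emission_distribution(copies, c)
            want = oracle_emission(copies, c)
            assert set(got) == set(want)
            for s in want:
                assert got[s] == pytest.approx(want[s], abs=1e-12)

    def test_gap_weighted_breakpoints(self):
        from paracopy import VariableSite

        sites = [VariableSite(10, "A", "G"), VariableSite(20, "A", "G"),
                 VariableSite(50, "A", "C")]
        w = ChimeraModel.gap_weights(sites)
        assert w == pytest.approx((0.25, 0.75))
        probs = emission_distribution(["AAA", "GGC"], c=0.2, breakpoint_weights=w)
        assert math.isclose(sum(probs.values()), 1.0, abs_tol=1e-12)
        # AGC arises only from parents (AAA, GGC) splitting in the narrow
        # first gap (weight 0.25); AAC only from the wide second gap (0.75)
        assert probs["AGC"] == pytest.approx(0.2 * 0.25 / 4)
        assert probs["AAC"] == pytest.approx(0.2 * 0.75 / 4)
        assert probs["AAC"] == pytest.approx(3 * probs["AGC"])


class TestSetLogLikelihood:
    def test_probability_one_emissions(self):
        assert set_log_likelihood({"AG": 50}, ["AG", "AG"], c=0.0) == 0.0

    def test_unreachable_combination_is_minus_inf(self):
        assert set_log_likelihood({"AT": 1}, ["AG", "AG"], c=0.0) == float("-inf")

    def test_hand_computed_mixture_value(self):
        counts = {"AG": 47, "CT": 48, "AT": 3, "CG": 2}
        ll = set_log_likelihood(counts, ["AG", "CT"], c=0.1)
        expected = (47 + 48) * math.log(0.475) + (3 + 2) * math.log(0.025)
        assert ll == pytest.approx(expected, rel=1e-12)


class TestProportionCI:
    def test_boundaries(self):
        assert combination_proportion_ci(0, 20)[0] == 0.0
        assert combination_proportion_ci(20, 20)[1] == 1.0

    def test_beta_quantile_closed_form(self):
        lo, hi = combination_proportion_ci(5, 50)
        assert lo == pytest.approx(stats.beta.ppf(0.025, 5, 46), rel=1e-12)
        assert hi == pytest.approx(stats.beta.ppf(0.975, 6, 45), rel=1e-12)

    def test_against_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for count, total in [(0, 10), (3, 17), (50, 51), (7, 7)]:
            lo, hi = combination_proportion_ci(count, total)
            slo, shi = proportion_confint(count, total, alpha=0.05, method="beta")
            assert lo == pytest.approx(slo, abs=1e-12)
            assert hi == pytest.approx(shi, abs=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            combination_proportion_ci(1, 0)


class TestCombine:
    def test_elementwise_sum(self):
        a = CombinationCounts(window=(0, 1), counts={"AG": 10})
        b = CombinationCounts(window=(0, 1), counts={"AG": 5, "CT": 1})
        merged = combine_datasets([a, b])
        assert merged.counts == {"AG": 15, "CT": 1}
        assert merged.total == a.total + b.total

    def test_identity(self):
        a = CombinationCounts(window=(0, 1), counts={"AG": 10})
        assert combine_datasets([a]).counts == a.counts

    def test_window_mismatch_rejected(self):
        a = CombinationCounts(window=(0, 1), counts={"AG": 1})
        b = CombinationCounts(window=(0, 2), counts={"AG": 1})
        with pytest.raises(ValueError, match="window"):
            combine_datasets([a, b])


def oracle_search(counts, k, c_grid):
    """Independent exhaustive ML search via the dict-based emission path."""
    observed = sorted(counts)
    best = (-math.inf, None, None)
    for ms in itertools.combinations_with_replacement(observed, k):
        for c in c_grid:
            ll = set_log_likelihood(counts, ms, c)
            if ll > best[0] + 1e-9:
                best = (ll, tuple(sorted(ms)), c)
    return best


class TestInference:
    def test_exact_proportions_with_no_chimeras(self):
        m = 1000
        counts = {"AG": 4 * m, "CT": 3 * m}
        est = infer_combination_set(counts, k=7, c_grid=[0.0])
        assert est.copies == ("AG",) * 4 + ("CT",) * 3

    def test_recovers_simulated_truth(self):
        ps = demo_paralogue_set()
        config = SimulationConfig(
            paralogue_set=ps, n_reads=5000, read_length=300,
            chimera_rate=0.05, seed=11,
        )
        _, cc = simulate_counts(config)
        est = infer_combination_set(cc, k=6)
        assert est.copies == ps.copies
        assert 0.0 <= est.chimera_rate <= 0.2

    def test_matches_independent_exhaustive_oracle(self):
        ps = demo_paralogue_set()
        config = SimulationConfig(
            paralogue_set=ps, n_reads=400, read_length=300,
            chimera_rate=0.08, seed=23,
        )
        _, cc = simulate_counts(config)
        grid = [0.0, 0.05, 0.1, 0.15]
        est = infer_combination_set(cc, k=6, c_grid=grid)
        ll, copies, c = oracle_search(cc.counts, 6, grid)
        assert est.copies == copies
        assert est.log_likelihood == pytest.approx(ll, rel=1e-10)
        assert est.chimera_rate == pytest.approx(c)

    def test_likelihood_peaks_at_truth_asymptotically(self):
        """At 50k reads the true set beats every single-copy perturbation."""
        ps = demo_paralogue_set()
        config = SimulationConfig(
            paralogue_set=ps, n_reads=50_000, read_length=300,
            chimera_rate=0.03, seed=31,
        )
        _, cc = simulate_counts(config)
        grid = np.arange(0, 0.101, 0.005)
        best_c_ll = max(
            set_log_likelihood(cc.counts, ps.copies, c) for c in grid
        )
        alphabet = sorted(cc.counts)
        for i in range(ps.k):
            for repl in alphabet:
                perturbed = list(ps.copies)
                if perturbed[i] == repl:
                    continue
                perturbed[i] = repl
                ll = max(
                    set_log_likelihood(cc.counts, perturbed, c) for c in grid
                )
                assert ll <= best_c_ll + 1e-9

    def test_small_datasets_less_reliable_than_combined(self):
        """Three ~90-read clone-scale datasets: their combination does not
        do worse than the worst individual dataset (sample-size effect)."""
        ps = demo_paralogue_set()
        hits_small = 0
        hits_combined = 0
        n_rep = 30
        for rep in range(n_rep):
            parts = []
            for d in range(3):
                config = SimulationConfig(
                    paralogue_set=ps, n_reads=90, read_length=300,
                    chimera_rate=0.03, seed=1000 + 10 * rep + d,
                )
                _, cc = simulate_counts(config)
                parts.append(cc)
                est = infer_combination_set(cc, k=6)
                hits_small += est.copies == ps.copies
            est = infer_combination_set(combine_datasets(parts), k=6)
            hits_combined += est.copies == ps.copies
        assert hits_combined / n_rep >= hits_small / (3 * n_rep)

    def test_candidate_space_guard(self):
        counts = {f"{a}{b}{c}": 1 for a in "ACGT" for b in "ACGT" for c in "ACGT"}
        with pytest.raises(ValueError, match="cap"):
            infer_combination_set(counts, k=10, max_multisets=100)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError, match="no observed"):
            infer_combination_set({}, k=6)

    def test_low_read_count_warns(self):
        with pytest.warns(UserWarning, match="weakly determined"):
            infer_combination_set({"AG": 2, "CT": 1}, k=6, c_grid=[0.0])

    def test_neighbour_alphabet_reaches_unobserved_copy(self):
        ps = demo_paralogue_set()
        # drop the rarest combination from the observations entirely
        counts = {"AAA": 500, "GAA": 160, "AGA": 170}
        est = infer_combination_set(
            counts, k=6, c_grid=[0.0], alphabet="neighbours", sites=ps.sites
        )
        assert len(est.copies) == 6

    def test_deterministic_tie_break(self):
        # two symmetric explanations; lexicographically smaller multiset wins
        counts = {"AG": 10, "GA": 10}
        est = infer_combination_set(counts, k=2, c_grid=[0.0])
        assert est.copies == ("AG", "GA")
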