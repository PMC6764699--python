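"""Dinucleotide chain fitting, simulation, analytic oracle, and Z-scores."""

import itertools
import math

import numpy as np
import pytest

from ascscan.null_models import (
    NUCS,
    DinucleotideModel,
    analytic_null,
    analytic_stop_probability,
    analytic_whole_utr_probability,
    compute_zscore,
    estimate_background_stop_rate,
    first_stop_probability,
    fit_dinucleotide_model,
    simulate_null,
)
from conftest import TT11, random_model

ALL_A = DinucleotideModel(
    np.array([1.0, 0, 0, 0]),
    np.array([[1.0, 0, 0, 0]] * 4),
)


class TestFit:
    def test_homogeneous_pool(self):
        m = fit_dinucleotide_model(["AAAA", "AAA"])
        assert m.initial[0] == 1.0
        assert m.transition[0, 0] == 1.0

    def test_alternating_pool(self):
        with pytest.warns(UserWarning):  # G and T rows never observed
            m = fit_dinucleotide_model(["ACACAC"])
        assert m.initial[0] == pytest.approx(0.5)
        assert m.initial[1] == pytest.approx(0.5)
        assert m.transition[0, 1] == 1.0  # A -> C
        assert m.transition[1, 0] == 1.0  # C -> A

    def test_matches_direct_count_oracle(self):
        rng = np.random.default_rng(42)
        windows = ["".join(rng.choice(list(NUCS), 100)) for _ in range(100)]
        m = fit_dinucleotide_model(windows)
        # independent dinucleotide tally, never crossing window boundaries
        counts = np.zeros((4, 4))
        mono = np.zeros(4)
        idx = {b: i for i, b in enumerate(NUCS)}
        for w in windows:
            for b in w:
                mono[idx[b]] += 1
            for a, b in zip(w, w[1:]):
                counts[idx[a], idx[b]] += 1
        np.testing.assert_allclose(m.initial, mono / mono.sum())
        np.testing.assert_allclose(m.transition, counts / counts.sum(1, keepdims=True))

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            fit_dinucleotide_model([])


class TestSimulateNull:
    def test_all_a_model_has_zero_stop_frequency(self):
        null = simulate_null(ALL_A, N=50, R=10, stop_set=TT11, rng_seed=0)
        assert all(null.mean[k] == 0 for k in range(1, 7))
        assert null.mean["whole"] == 0

    def test_uniform_model_near_three_in_sixtyfour(self, uniform_model):
        null = simulate_null(uniform_model, N=500, R=200, stop_set=TT11, rng_seed=1)
        se = 3 * math.sqrt(3 / 64 * (1 - 3 / 64) / (500 * 200))
        for k in range(1, 7):
            assert abs(null.mean[k] - 3 / 64) < se

    def test_matches_analytic_oracle_for_random_models(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            m = random_model(rng)
            null = simulate_null(m, N=200, R=100, stop_set=TT11, rng_seed=rng)
            for k in (1, 3, 6):
                f0 = analytic_stop_probability(m, k, TT11)
                mc_se = null.sd[k] / math.sqrt(null.replicates)
                assert abs(null.mean[k] - f0) < 3 * max(mc_se, 1e-6)

    def test_whole_utr_matches_transfer_matrix(self, uniform_model):
        # iid chain: P(>=1 stop in 6 codons) = 1 - (61/64)^6 exactly
        assert analytic_whole_utr_probability(uniform_model, TT11) == pytest.approx(
            1 - (61 / 64) ** 6
        )
        null = simulate_null(uniform_model, N=500, R=200, stop_set=TT11, rng_seed=3)
        assert null.mean["whole"] == pytest.approx(1 - (61 / 64) ** 6, abs=0.01)

    def test_conditioning_on_t_raises_position_one_stop_rate(self):
        # a sticky chain keeps the forced first base T through to the +1
        # codon start; since every stop starts with T, the conditioned
        # null mean at +1 rises above the unconditioned one
        T = np.full((4, 4), 0.1 / 3) + np.eye(4) * (0.9 - 0.1 / 3)
        T /= T.sum(1, keepdims=True)
        m = DinucleotideModel(np.full(4, 0.25), T)
        f_cond = analytic_stop_probability(m, 1, TT11, condition_first_base="T")
        f_free = analytic_stop_probability(m, 1, TT11)
        assert f_cond > f_free


class TestAnalyticStopProbability:
    def test_uniform_is_three_in_sixtyfour(self, uniform_model):
        for k in range(1, 7):
            assert analytic_stop_probability(uniform_model, k, TT11) == pytest.approx(3 / 64)

    def test_all_a_is_zero(self):
        assert analytic_stop_probability(ALL_A, 1, TT11) == 0

    def test_equals_exhaustive_enumeration(self):
        # position +1 codon occupies bases 3..5: enumerate all 4^6 prefixes
        rng = np.random.default_rng(11)
        m = random_model(rng)
        total = 0.0
        for seq in itertools.product(range(4), repeat=6):
            p = m.initial[seq[0]]
            for a, b in zip(seq, seq[1:]):
                p *= m.transition[a, b]
            codon = "".join(NUCS[i] for i in seq[3:6])
            if codon in TT11:
                total += p
        assert analytic_stop_probability(m, 1, TT11) == pytest.approx(total, rel=1e-10)


class TestZScore:
    def test_observed_equals_mean(self, uniform_model):
        null = analytic_null(uniform_model, 100, TT11)
        assert compute_zscore(null.mean[1], null, 1) == 0

    def test_two_sd_above(self, uniform_model):
        null = analytic_null(uniform_model, 100, TT11)
        assert compute_zscore(null.mean[2] + 2 * null.sd[2], null, 2) == pytest.approx(2)

    def test_zero_sd_flags_infinite(self):
        null = analytic_null(ALL_A, 100, TT11)
        assert compute_zscore(0.0, null, 1) == 0
        assert compute_zscore(0.1, null, 1) == math.inf

    def test_calibrated_on_self_generated_genomes(self):
        # genomes drawn from their own fitted chain should give |Z| > 1.96
        # in roughly 5% of cases
        from ascscan import enrichment as en
        from ascscan import synthetic_data as sd

        rng = np.random.default_rng(5)
        hits = trials = 0
        for _ in range(40):
            cfg = sd.SyntheticConfig(seed=int(rng.integers(2**31)), n_genes=800)
            uset, _ = sd.generate_utr_set(cfg)
            model = fit_dinucleotide_model([r.downstream_seq for r in uset.records])
            null = analytic_null(model, uset.n_genes, uset.stop_set)
            obs = en.positional_asc_frequencies(uset)
            for k in range(1, 7):
                hits += abs(compute_zscore(obs.freq[k], null, k)) > 1.96
                trials += 1
        rate = hits / trials
        assert 0.01 < rate < 0.10


class TestBackgroundStopRate:
    def test_hand_count(self):
        # 2 genes x 6 codons, 3 stops total -> 3/12
        windows = ["TAAGCGTGACCGGCCTAG", "GCAGCAGCAGCAGCAGCA"]
        assert estimate_background_stop_rate(windows, TT11) == pytest.approx(3 / 12)

    def test_no_stops(self):
        assert estimate_background_stop_rate(["GCGCGC"], TT11) == 0

    def test_matches_per_gene_scan_oracle(self):
        rng = np.random.default_rng(3)
        windows = ["".join(rng.choice(list(NUCS), 99)) for _ in range(50)]
        stops = positions = 0
        for w in windows:
            for i in range(0, 99, 3):
                stops += w[i : i + 3] in TT11
                positions += 1
        assert estimate_background_stop_rate(windows, TT11) == pytest.approx(stops / positions)

    def test_span_excludes_short_windows(self):
        windows = ["TAA" * 10, "TAA"]  # second too short for span 12
        p = estimate_background_stop_rate(windows, TT11, span_nt=12)
        assert p == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            estimate_background_stop_rate([], TT11)


class TestFirstStopProbability:
    @pytest.mark.parametrize("p,n,expected", [(0.1, 1, 0.1), (0.1, 3, 0.081), (0.5, 2, 0.25)])
    def test_formula(self, p, n, expected):
        assert first_stop_probability(p, n) == pytest.approx(expected)

    def test_geometric_series_sums_to_one(self):
        for p in (0.01, 0.3, 1.0):
            total = sum(first_stop_probability(p, n) for n in range(1, 10_000))
            assert total == pytest.approx(1.0, abs=1e-6 if p > 0.01 else 1e-2)


class TestChainProperties:
    """Property tests over arbitrary chains (hypothesis, derandomised)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_analytic_probability_equals_enumeration(self, seed):
        import itertools

        m = random_model(np.random.default_rng(seed))
        total = 0.0
        for seq in itertools.product(range(4), repeat=6):
            p = m.initial[seq[0]]
            for a, b in zip(seq, seq[1:]):
                p *= m.transition[a, b]
            if "".join(NUCS[i] for i in seq[3:6]) in TT11:
                total += p
        assert analytic_stop_probability(m, 1, TT11) == pytest.approx(total, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_whole_utr_probability_bounded_by_union(self, seed):
        m = random_model(np.random.default_rng(seed))
        whole = analytic_whole_utr_probability(m, TT11)
        positional = [analytic_stop_probability(m, k, TT11) for k in range(1, 7)]
        assert 0 <= whole <= 1
        assert whole <= sum(positional) + 1e-12
        assert whole >= max(positional) - 1e-12
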