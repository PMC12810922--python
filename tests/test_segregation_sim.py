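"""Segregation simulator: founder rules, division mechanics, population behavior."""

import random
from collections import Counter

import numpy as np
import pytest

from mitofast.segregation_sim import (
    NucleoidCell,
    SimConfig,
    SimResult,
    _divide_alleles,
    _split_alleles,
    divide_cell,
    division_probability,
    growth_rate_ratio,
    init_founder,
    run_replicates,
    simulate_population,
    sweep_ratios,
)


class TestInitFounder:
    @pytest.mark.parametrize(
        "ratio, ones",
        [
            (0.1, 3),    # worked example: 32 * 0.1/1.1 = 2.91 -> 3 ones, 29 zeros
            (1.0, 16),   # symmetric cross leaves the alternating string unchanged
            (0.71, 13),  # round(32 * 0.71/1.71) = round(13.29)
        ],
    )
    def test_ones_count_from_ratio(self, ratio, ones):
        cell = init_founder(32, ratio, random.Random(0))
        assert sum(cell.alleles) == ones
        assert len(cell.alleles) == 32
        assert cell.h == ones / 32

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            init_founder(32, -0.1, random.Random(0))

    def test_ratio_one_is_exact_alternation(self):
        cell = init_founder(32, 1.0, random.Random(0))
        assert cell.alleles == [1, 0] * 16


class TestGrowthCoupling:
    def test_pure_reference_grows_at_wt_rate(self):
        assert growth_rate_ratio(0.0, 0.93) == 1.0
        assert division_probability(1.0) == 1.0

    def test_homoplasmic_other_gets_strain_rate(self):
        assert growth_rate_ratio(1.0, 0.93) == pytest.approx(0.93)
        assert division_probability(0.93) == pytest.approx(2**0.93 - 1)

    def test_midpoint_linear(self):
        assert growth_rate_ratio(0.5, 0.98) == pytest.approx(0.99)

    def test_faster_than_wt_clamped(self):
        assert division_probability(1.03) == 1.0


class TestDivideCell:
    def test_split_conserves_allele_multiset(self):
        rng = random.Random(0)
        alleles = init_founder(32, 0.71, rng).alleles
        for _ in range(200):
            m, d = _split_alleles(alleles, 5, rng)
            assert Counter(m) + Counter(d) == Counter(alleles)
            assert len(m) > 0 and len(d) > 0

    def test_children_replenished_to_n(self):
        rng = random.Random(1)
        cell = init_founder(32, 0.5, rng)
        m, d = divide_cell(cell, nspl=5, rng=rng)
        assert m.n_nucleoids == 32 and d.n_nucleoids == 32
        assert m.divisions_done == 1 and d.divisions_done == 0

    def test_post_replicative_cell_refuses_division(self):
        cell = NucleoidCell(alleles=[1, 0] * 16, divisions_done=11)
        with pytest.raises(ValueError, match="post-replicative"):
            divide_cell(cell, nspl=5, rng=random.Random(0), ndau=11)

    def test_daughter_h_unbiased_at_half(self):
        rng = random.Random(2)
        alleles = [1, 0] * 16
        hs = []
        for _ in range(10_000):
            _, d = _divide_alleles(alleles, 5, rng)
            hs.append(sum(d) / 32)
        se = np.std(hs) / np.sqrt(len(hs))
        assert abs(np.mean(hs) - 0.5) < 3 * se

    @pytest.mark.parametrize("alleles", [[1] * 6 + [0] * 26, [1, 1] + [0] * 30])
    def test_pair_mean_h_unbiased_off_half(self, alleles):
        """Mean of (h_mother + h_daughter)/2 equals parent h even for clustered
        minorities, where resident-only duplication would drift toward 1/2."""
        rng = random.Random(3)
        h = sum(alleles) / len(alleles)
        vals = []
        for _ in range(20_000):
            m, d = _divide_alleles(list(alleles), 5, rng)
            vals.append((sum(m) + sum(d)) / 64)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - h) < 3 * se


class TestSmallInstanceOracle:
    def test_n2_enumeration(self):
        """N=2, nspl=1, parent [1,0]: the split sends the 1 to mother or daughter
        with probability 1/2 each, and each child's duplicate templates a parental
        nucleoid uniformly, so exact child-h probabilities are enumerable:
        the child holding the 1 has h=1 w.p. 1/2 and h=1/2 w.p. 1/2;
        the other child has h=0 w.p. 1/2 and h=1/2 w.p. 1/2."""
        rng = random.Random(4)
        counts = Counter()
        trials = 50_000
        for _ in range(trials):
            m, d = _divide_alleles([1, 0], 1, rng)
            counts[(sum(m) / 2, sum(d) / 2)] += 1
        # mother holds the original 1 w.p. 1/2, independent of both duplicates
        expected = {
            (1.0, 0.0): 1 / 8, (1.0, 0.5): 1 / 8, (0.5, 0.0): 1 / 8, (0.5, 0.5): 2 / 8,
            (0.0, 1.0): 1 / 8, (0.5, 1.0): 1 / 8, (0.0, 0.5): 1 / 8,
        }
        assert sum(expected.values()) == 1.0
        for outcome, p in expected.items():
            sd = np.sqrt(trials * p * (1 - p))
            assert abs(counts[outcome] - trials * p) < 4 * sd, outcome


class TestPopulation:
    def test_forced_division_cell_count(self):
        # g_other=1 makes p=1: every cell divides every step, so 2^ngen cells
        cfg = SimConfig(ratio=1.0, g_other=1.0, ngen=2, ndau=11, n_founders=1, n_runs=1)
        res = simulate_population(cfg, seed=0)
        assert res.final_cells[0] == 4

    def test_neutral_symmetric_cross_centered(self):
        cfg = SimConfig(ratio=1.0, g_other=1.0, ngen=6, n_founders=10, n_runs=40, seed=5)
        res = run_replicates(cfg)
        se = res.sd / np.sqrt(cfg.n_runs)
        assert abs(res.grand_mean - 0.5) < 3 * se

    @pytest.mark.parametrize("ratio", [0.25, 0.5, 1.0])
    def test_neutral_martingale(self, ratio):
        """With g_other=1 the expected population mean h equals the founder h."""
        cfg = SimConfig(ratio=ratio, g_other=1.0, ngen=7, n_founders=10, n_runs=200, seed=6)
        h0 = sum(init_founder(32, ratio, random.Random(0)).alleles) / 32
        res = run_replicates(cfg)
        se = res.sd / np.sqrt(cfg.n_runs)
        assert abs(res.grand_mean - h0) < 3 * se

    def test_growth_penalty_depletes_variant(self):
        """g_other < 1 shifts the final mean below the founder fraction."""
        cfg = SimConfig(ratio=1.0, g_other=0.85, ngen=8, n_founders=10, n_runs=200, seed=7)
        res = run_replicates(cfg)
        se = res.sd / np.sqrt(cfg.n_runs)
        assert res.grand_mean < 0.5 - 2 * se

    def test_stochastic_variance_present(self):
        cfg = SimConfig(ratio=0.5, g_other=1.0, ngen=6, n_founders=5, n_runs=30, seed=8)
        assert run_replicates(cfg).sd > 0

    def test_compiled_engine_matches_reference_implementation(self):
        """The compiled generation kernel and the interpreted reference engine
        implement the same model: their mean_h distributions must agree."""
        from mitofast.segregation_sim import _simulate_once, _simulate_once_python

        cfg = SimConfig(ratio=0.71, g_other=0.95, ngen=6, n_founders=5, n_runs=1)
        fast = np.array([_simulate_once(cfg, s)[0] for s in range(120)])
        ref = np.array([_simulate_once_python(cfg, s)[0] for s in range(120)])
        se = np.sqrt(fast.var() / len(fast) + ref.var() / len(ref))
        assert abs(fast.mean() - ref.mean()) < 3 * se
        # cell counts are identically distributed too (division prob law)
        nf = np.array([_simulate_once(cfg, s)[1] for s in range(60)])
        nr = np.array([_simulate_once_python(cfg, s)[1] for s in range(60)])
        se_n = np.sqrt(nf.var() / len(nf) + nr.var() / len(nr))
        assert abs(nf.mean() - nr.mean()) < 3 * se_n

    def test_seeded_determinism(self):
        cfg = SimConfig(ratio=0.71, g_other=0.98, ngen=5, n_founders=5, n_runs=10, seed=9)
        a = run_replicates(cfg)
        b = run_replicates(cfg)
        assert np.array_equal(a.mean_h, b.mean_h)
        assert np.array_equal(a.final_cells, b.final_cells)


class TestSweep:
    def test_mean_h_nondecreasing_in_ratio(self):
        cfg = SimConfig(ratio=0.5, g_other=0.98, ngen=6, n_founders=10, n_runs=1, seed=10)
        sweep = sweep_ratios(cfg, ratios=[0.2, 0.5, 1.0], n_runs_per_ratio=60)
        means = sweep.mean_per_ratio()
        # monotone within Monte-Carlo noise: allow 2 pooled SEs of slack
        for a, b, ra, rb in zip(means, means[1:], sweep.ratios, sweep.ratios[1:]):
            se = np.sqrt(
                np.var(sweep.mean_h[float(ra)]) / 60 + np.var(sweep.mean_h[float(rb)]) / 60
            )
            assert b >= a - 2 * se

    def test_observed_zero_matches_smallest_ratio(self):
        cfg = SimConfig(ratio=0.5, g_other=1.0, ngen=4, n_founders=5, n_runs=1, seed=11)
        sweep = sweep_ratios(cfg, ratios=[0.1, 0.5, 1.0], n_runs_per_ratio=5)
        assert sweep.best_match(0.0) == 0.1

    def test_empty_grid_rejected(self):
        cfg = SimConfig(ratio=0.5, n_runs=1)
        with pytest.raises(ValueError, match="empty"):
            sweep_ratios(cfg, ratios=[])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ratio": -0.2},
            {"ratio": 0.5, "g_other": 0.0},
            {"ratio": 0.5, "n_nucleoids": 31},
            {"ratio": 0.5, "nspl": 32},
            {"ratio": 0.5, "ngen": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
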