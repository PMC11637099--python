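"""Stochastic simulator stages against binomial/Poisson oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prepsim import builtin_protocol, run_cascade, table_params
from prepsim.simulate import (
    FragmentPopulation,
    SPRIRetentionCurve,
    SimulationOptions,
    apply_losses,
    calibrate_retention,
    electropherogram,
    simulate_assay,
    simulate_fragmentation,
    simulate_ligation,
    simulate_pcr,
    simulate_spri,
)


_CODE = {"insert": 0, "adapter_ligated_insert": 1, "adapter_dimer": 2}


def single_length_population(length=400, count=10**6, species="insert"):
    return FragmentPopulation(
        np.array([length]), np.array([_CODE[species]], dtype=np.int8),
        np.array([count]),
    )


class TestFragmentation:
    def test_fixed_distribution_is_degenerate(self):
        pop = simulate_fragmentation(10**5, "fixed", 260, 0.0)
        assert pop.total_count() == 10**5
        assert list(pop.lengths) == [260]

    def test_lognormal_mean_within_3_se(self):
        n, mean, cv = 10**5, 250.0, 0.3
        pop = simulate_fragmentation(n, "lognormal", mean, cv, seed=1)
        se = cv * mean / math.sqrt(n)
        assert abs(pop.mean_length() - mean) < 3 * se

    def test_zero_molecules_gives_empty_population(self):
        pop = simulate_fragmentation(0, "lognormal", 250, 0.3, seed=1)
        assert pop.total_count() == 0

    def test_fixed_with_spread_rejected(self):
        with pytest.raises(ValueError, match="cv"):
            simulate_fragmentation(10, "fixed", 260, 0.3)


class TestLigation:
    def test_complete_ligation_no_dimers(self):
        pop = simulate_fragmentation(1000, "fixed", 260, 0.0)
        out = simulate_ligation(pop, 1.0, 0.0, 70, seed=0)
        assert out.total_count("adapter_ligated_insert") == 1000
        assert out.total_count("insert") == 0
        assert out.total_count("adapter_dimer") == 0
        assert list(out.select("adapter_ligated_insert").lengths) == [400]

    def test_binomial_thinning_oracle(self):
        n, eta = 10**5, 0.60
        pop = simulate_fragmentation(n, "fixed", 260, 0.0)
        out = simulate_ligation(pop, eta, 0.0, 70, seed=2)
        sd = math.sqrt(n * eta * (1 - eta))
        ligated = out.total_count("adapter_ligated_insert")
        assert abs(ligated - n * eta) < 3 * sd
        # failures are retained, not dropped
        assert ligated + out.total_count("insert") == n

    def test_expected_ligated_count_matches_cascade_factor(self, mech_params):
        # replicate mean tracks eta_lig * N within binomial error
        n = 20_000
        pop = simulate_fragmentation(n, "lognormal", mech_params.l_bpi,
                                     0.3, seed=3)
        counts = [
            simulate_ligation(pop, mech_params.eta_lig, 0.0,
                              mech_params.l_A, seed=s)
            .total_count("adapter_ligated_insert")
            for s in range(30)
        ]
        se = math.sqrt(n * 0.6 * 0.4 / 30)
        assert abs(np.mean(counts) - n * mech_params.eta_lig) < 3 * se

    def test_dimers_form_at_twice_adapter_length(self):
        pop = simulate_fragmentation(10**4, "fixed", 260, 0.0)
        out = simulate_ligation(pop, 0.5, 0.1, 70, seed=4)
        dimers = out.select("adapter_dimer")
        assert list(dimers.lengths) == [140]
        sd = math.sqrt(10**4 * 0.1)
        assert abs(dimers.total_count() - 1000) < 4 * sd


class TestRetentionCalibration:
    def test_single_length_closed_form(self):
        pop = single_length_population(400, 10**6, "adapter_ligated_insert")
        curve = calibrate_retention(200, 20, 0.73, pop)
        logistic = 1.0 / (1.0 + math.exp(-(400 - 200) / 20))
        assert curve.eta_max == pytest.approx(0.73 / logistic, rel=1e-12)
        assert float(curve.retention(400)) == pytest.approx(0.73, abs=1e-9)

    def test_population_weighted_mean_hits_target(self):
        pop = simulate_fragmentation(10**5, "lognormal", 400, 0.3, seed=5)
        lib = FragmentPopulation(pop.lengths,
                                 np.ones(len(pop.lengths), dtype=np.int8),
                                 pop.counts)
        curve = calibrate_retention(200, 20, 0.73, lib)
        mean_ret = float(
            (curve.retention(lib.lengths) * lib.counts).sum()
            / lib.counts.sum()
        )
        assert mean_ret == pytest.approx(0.73, abs=1e-6)

    def test_zero_target_rejected(self):
        pop = single_length_population(400, 100, "adapter_ligated_insert")
        with pytest.raises(ValueError, match="target_eta_wash"):
            calibrate_retention(200, 20, 0.0, pop)

    def test_unachievable_target_reports_attainable_maximum(self):
        pop = single_length_population(150, 100, "adapter_ligated_insert")
        with pytest.raises(ValueError, match="attainable maximum"):
            calibrate_retention(200, 20, 0.9, pop)


class TestSPRI:
    def test_retain_all_limit(self):
        pop = simulate_fragmentation(10**4, "lognormal", 300, 0.3, seed=6)
        curve = SPRIRetentionCurve(l50=-1000.0, s=1.0, eta_max=1.0)
        out = simulate_spri(pop, curve, seed=7)
        assert out.total_count() == pop.total_count()

    def test_binomial_survival_oracle(self):
        pop = single_length_population(400, 10**6, "adapter_ligated_insert")
        curve = calibrate_retention(200, 20, 0.73, pop)
        out = simulate_spri(pop, curve, seed=8)
        sd = math.sqrt(10**6 * 0.73 * 0.27)
        assert abs(out.total_count() - 0.73e6) < 3 * sd

    def test_wash_preferentially_removes_dimers(self):
        lengths = np.array([140, 400])
        species = np.array([2, 1], dtype=np.int8)  # dimer, ligated insert
        counts = np.array([50_000, 50_000])
        pop = FragmentPopulation(lengths, species, counts)
        curve = calibrate_retention(200, 20, 0.73, pop)
        out = simulate_spri(pop, curve, seed=9)
        frac_before = 0.5
        frac_after = out.total_count("adapter_dimer") / out.total_count()
        assert frac_after < frac_before / 5


class TestPCR:
    def test_mean_multiplier(self):
        pop = single_length_population(400, 10**6, "adapter_ligated_insert")
        out = simulate_pcr(pop, 0.95, 8, mode="paper", seed=10)
        n_trials = 10**6 * 256
        sd = math.sqrt(n_trials * 0.95 * 0.05)
        assert abs(out.total_count() - 243.2e6) < 3 * sd

    def test_zero_cycles_paper_mode_thins(self):
        pop = single_length_population(400, 10**6, "adapter_ligated_insert")
        out = simulate_pcr(pop, 0.95, 0, mode="paper", seed=11)
        sd = math.sqrt(10**6 * 0.95 * 0.05)
        assert abs(out.total_count() - 0.95e6) < 3 * sd

    def test_per_cycle_duplication_probability(self):
        # p_c = (2^8 * 0.95)^(1/8) - 1
        assert (2**8 * 0.95) ** (1 / 8) - 1 == pytest.approx(0.987, abs=1e-3)

    def test_per_cycle_mode_matches_expectation(self):
        pop = single_length_population(400, 10**5, "adapter_ligated_insert")
        counts = [
            simulate_pcr(pop, 0.95, 8, mode="per_cycle", seed=s).total_count()
            for s in range(20)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(20)
        assert abs(mean - 243.2e5) < 4 * se

    def test_per_cycle_infeasible_efficiency_reported(self):
        pop = single_length_population(400, 100, "adapter_ligated_insert")
        with pytest.raises(ValueError, match="feasible eta_PCR"):
            simulate_pcr(pop, 0.001, 8, mode="per_cycle", seed=0)

    def test_bare_inserts_do_not_amplify(self):
        pop = FragmentPopulation(np.array([260]), np.array([0], dtype=np.int8),
                                 np.array([1000]))
        out = simulate_pcr(pop, 0.95, 8, seed=12)
        assert out.total_count("insert") == 1000


class TestLosses:
    def test_no_loss_identity(self):
        pop = single_length_population(400, 10**5, "adapter_ligated_insert")
        out = apply_losses(pop, 0.0, 0.0, seed=13)
        assert out.total_count() == 10**5

    def test_total_loss_empties_population(self):
        pop = single_length_population(400, 10**5, "adapter_ligated_insert")
        assert apply_losses(pop, 1.0, 0.5, seed=14).total_count() == 0

    def test_survival_probability_oracle(self):
        pop = single_length_population(400, 10**6, "adapter_ligated_insert")
        out = apply_losses(pop, 0.05, 0.15, seed=15)
        p = 0.95 * 0.85
        sd = math.sqrt(10**6 * p * (1 - p))
        assert abs(out.total_count() - 8.075e5) < 3 * sd


class TestElectropherogram:
    def test_single_length_single_bin(self):
        pop = single_length_population(400, 1000, "adapter_ligated_insert")
        hist, in_range = electropherogram(pop, bin_width=50)
        assert len(hist) == 1
        (lo, hi), frac = hist[0]
        assert lo <= 400 < hi and frac == 1.0 and in_range == 1.0

    def test_mixture_in_range_fraction(self):
        # 10% of mass at 150 bp (below range), 90% at 400 bp
        pop = FragmentPopulation(
            np.array([150, 400]), np.array([2, 1], dtype=np.int8),
            np.array([600, 2025]),
        )
        # masses: 150*600 = 90000, 400*2025 = 810000 -> 10% / 90%
        _, in_range = electropherogram(pop, bin_width=50)
        assert in_range == pytest.approx(0.9, abs=1e-12)

    def test_mass_fractions_sum_to_one(self):
        pop = simulate_fragmentation(10**4, "lognormal", 300, 0.4, seed=16)
        hist, _ = electropherogram(pop, bin_width=25)
        assert sum(f for _, f in hist) == pytest.approx(1.0, abs=1e-9)

    def test_empty_population_flagged_not_raised(self):
        hist, in_range = electropherogram(
            FragmentPopulation.empty(), bin_width=50
        )
        assert hist == [] and in_range == 0.0


class TestFullAssay:
    def test_seed_determinism(self, protocol, params):
        a = simulate_assay(protocol, params, seed=123)
        b = simulate_assay(protocol, params, seed=123)
        assert a.C_f == b.C_f
        assert a.stage_counts == b.stage_counts
        assert np.array_equal(a.final_population.lengths,
                              b.final_population.lengths)
        assert np.array_equal(a.final_population.counts,
                              b.final_population.counts)

    def test_different_seeds_differ(self, mech_params):
        proto = builtin_protocol("mechanical")
        a = simulate_assay(proto, mech_params, seed=1)
        b = simulate_assay(proto, mech_params, seed=2)
        assert a.C_f != b.C_f

    def test_stage_counts_track_cascade(self, protocol, params):
        """Single-run stage counts stay within 4 sigma of the cascade chain."""
        opts = SimulationOptions(n_founders=100_000)
        result = simulate_assay(protocol, params, opts, seed=99)
        n = opts.n_founders
        sc = result.stage_counts
        checks = [
            ("ligated", n * params.eta_lig,
             math.sqrt(n * params.eta_lig * (1 - params.eta_lig))),
            ("post_wash1", n * params.eta_lig * params.eta_wash,
             math.sqrt(n * params.eta_lig * params.eta_wash)),
        ]
        for name, expected, sd in checks:
            assert abs(sc[name] - expected) < 4 * sd, name

    def test_expected_concentration_matches_cascade(self, protocol, params):
        cascade_cf = run_cascade(params).C_f
        cfs = [
            simulate_assay(protocol, params, seed=s).C_f for s in range(40)
        ]
        se = np.std(cfs, ddof=1) / math.sqrt(len(cfs))
        assert abs(np.mean(cfs) - cascade_cf) < 4 * se

    def test_no_ligation_yields_empty_library(self, mech_params):
        import dataclasses
        proto = builtin_protocol("mechanical")
        params = dataclasses.replace(mech_params, eta_lig=0.0)
        opts = SimulationOptions(n_founders=5000, dimer_rate=0.5)
        result = simulate_assay(proto, params, opts, seed=5)
        assert result.m_out == 0.0
        assert result.C_f == 0.0
        # any surviving mass is adapter-dimer or unligated insert
        assert result.final_population.total_count("adapter_ligated_insert") == 0

    def test_dimer_percentage_is_total_before_wash(self):
        pop = simulate_fragmentation(5000, "fixed", 260, 0.0)
        out = simulate_ligation(pop, 0.0, 0.5, 70, seed=6)
        dimer_mass = out.total_mass("adapter_dimer")
        insert_mass = out.total_mass("insert")
        assert out.total_mass("adapter_ligated_insert") == 0.0
        assert dimer_mass / (dimer_mass + insert_mass) < 1.0  # inserts remain

    def test_final_dimer_fraction_in_expected_band(self, protocol, params):
        """Default dimer rate lands the final dimer mass near 0.1-0.5%."""
        pcts = [
            simulate_assay(protocol, params, seed=s).percent_adapter_dimer
            for s in range(10)
        ]
        assert 0.02 < np.mean(pcts) < 1.0

    @settings(deadline=None, max_examples=10)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_thinning_stages_never_increase_counts(self, seed):
        pop = simulate_fragmentation(5000, "lognormal", 300, 0.3, seed=seed)
        lib = FragmentPopulation(pop.lengths,
                                 np.ones(len(pop.lengths), dtype=np.int8),
                                 pop.counts)
        before = dict(zip(lib.lengths.tolist(), lib.counts.tolist()))
        curve = calibrate_retention(200, 20, 0.73, lib)
        washed = simulate_spri(lib, curve, seed=seed)
        for length, count in zip(washed.lengths.tolist(),
                                 washed.counts.tolist()):
            assert count <= before[length]
        lost = apply_losses(lib, 0.05, 0.15, seed=seed)
        for length, count in zip(lost.lengths.tolist(), lost.counts.tolist()):
            assert count <= before[length]
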