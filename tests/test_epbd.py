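"""Unit and property tests for the breathing simulator."""

import math

import numpy as np
import pytest

from dnabreathing import epbd
from dnabreathing.epbd import (
    DISPLACEMENT_SCALE,
    FLIP_THRESHOLD,
    DisplacementState,
    DuplexSequence,
    EPBDParams,
    MCMCConfig,
    mcmc_sweep,
    onsite_energy,
    oracle_expectation,
    simulate,
    stacking_energy,
    total_energy,
)

from conftest import random_sequence


class TestEnergies:
    def test_onsite_minimum_and_plateau(self, params):
        assert onsite_energy(0.0, "A", params) == 0.0
        assert onsite_energy(0.0, "G", params) == 0.0
        # Morse dissociation limit -> well depth
        assert onsite_energy(1e6, "A", params) == pytest.approx(params.D_AT)
        assert onsite_energy(1e6, "C", params) == pytest.approx(params.D_GC)

    def test_onsite_closed_form_value(self, params):
        # frozen from an independent high-precision evaluation of
        # D*(exp(-a*y)-1)^2 at y=0.5, G with D=0.075, a=6.9
        assert onsite_energy(0.5, "G", params) == pytest.approx(0.070313738450468445, rel=1e-12)

    def test_onsite_rejects_unknown_base(self, params):
        with pytest.raises(ValueError):
            onsite_energy(0.1, "N", params)

    def test_stacking_vanishes_for_equal_displacements(self, params):
        for y in (-1.0, 0.0, 3.7):
            assert stacking_energy(y, y, "AT", params) == 0.0

    def test_stacking_harmonic_limit(self):
        p = EPBDParams(rho=0.0)
        assert stacking_energy(1.3, 0.1, "GC", p) == pytest.approx(0.5 * p.k_stack * 1.2 ** 2)

    def test_stacking_closed_form_value(self, params):
        # frozen: (k/2)(1 + rho e^{-beta(y_n+y_prev)})(dy)^2 at y=(1,0)
        assert stacking_energy(1.0, 0.0, "AA", params) == pytest.approx(
            0.030117202242967838, rel=1e-12
        )

    def test_dinucleotide_scale_multiplies_stacking(self, params):
        scale = {d: 1.0 for d in params.dinucleotide_scale}
        scale["AA"] = 2.0
        p = EPBDParams(dinucleotide_scale=scale)
        assert stacking_energy(1.0, 0.0, "AA", p) == pytest.approx(
            2 * stacking_energy(1.0, 0.0, "AT", p)
        )

    def test_total_energy_decomposition(self, params):
        rng = np.random.default_rng(0)
        seq = DuplexSequence("s", "ACGT")
        y = rng.uniform(-0.5, 3.0, size=4)
        expected = sum(onsite_energy(y[n], seq.bases[n], params) for n in range(4))
        expected += sum(
            stacking_energy(y[n], y[n - 1], seq.bases[n - 1:n + 1], params) for n in range(1, 4)
        )
        assert total_energy(DisplacementState(y), seq, params) == pytest.approx(expected)
        assert total_energy(DisplacementState(np.zeros(4)), seq, params) == 0.0

    def test_total_energy_length_mismatch(self, params):
        with pytest.raises(ValueError):
            total_energy(DisplacementState(np.zeros(3)), DuplexSequence("s", "ACGT"), params)


class TestValidation:
    def test_duplex_rejects_ambiguity_codes(self):
        with pytest.raises(ValueError):
            DuplexSequence("s", "ACGTN")
        with pytest.raises(ValueError):
            DuplexSequence("s", "A")

    def test_params_require_gc_stronger_than_at(self):
        with pytest.raises(ValueError):
            EPBDParams(D_GC=0.04)  # weaker than D_AT

    def test_config_rejects_empty_production(self):
        with pytest.raises(ValueError):
            MCMCConfig(production_sweeps=0)
        with pytest.raises(ValueError):
            MCMCConfig(production_sweeps=3, thinning=4)


class TestSweep:
    def test_sweep_deterministic_given_rng_state(self, params):
        seq = DuplexSequence("s", "ACG")
        cfg = MCMCConfig()
        states = []
        for _ in range(2):
            state = DisplacementState(np.zeros(3))
            rng = np.random.default_rng(99)
            for _ in range(5):
                state, _ = mcmc_sweep(state, seq, params, cfg, rng)
            states.append(state.y)
        np.testing.assert_array_equal(states[0], states[1])

    def test_tiny_proposals_accepted(self, params):
        seq = DuplexSequence("s", "ACGTACGT")
        cfg = MCMCConfig(proposal_sigma=1e-8)
        state, accepted = mcmc_sweep(
            DisplacementState(np.zeros(8)), seq, params, cfg, np.random.default_rng(1)
        )
        assert accepted == 8  # null proposals barely change energy
        np.testing.assert_allclose(state.y, 0.0, atol=1e-6)

    def test_zero_temperature_only_descends(self):
        p = EPBDParams(temperature=1e-9)
        seq = DuplexSequence("s", "ATAT")
        cfg = MCMCConfig()
        rng = np.random.default_rng(5)
        state = DisplacementState(np.full(4, 2.0))
        energy = total_energy(state, seq, p)
        for _ in range(30):
            state, _ = mcmc_sweep(state, seq, p, cfg, rng)
            new_energy = total_energy(state, seq, p)
            assert new_energy <= energy + 1e-12
            energy = new_energy

    def test_walls_respected(self, params):
        seq = DuplexSequence("s", "ATATAT")
        cfg = MCMCConfig(y_min=-0.5, y_max=1.5, proposal_sigma=2.0)
        rng = np.random.default_rng(2)
        state = DisplacementState(np.zeros(6))
        for _ in range(200):
            state, _ = mcmc_sweep(state, seq, params, cfg, rng)
            assert np.all(state.y >= -0.5) and np.all(state.y <= 1.5)


class TestSimulate:
    def test_invariants_on_random_sequences(self, params, quick_mcmc):
        rng = np.random.default_rng(11)
        for i in range(5):
            seq = DuplexSequence(f"r{i}", random_sequence(rng, 30))
            prof, tens = simulate(seq, params, quick_mcmc.with_seed(i))
            prof.validate()
            tens.validate(prof)

    def test_bit_identical_reproduction(self, params, quick_mcmc):
        seq = DuplexSequence("s", "ACGTTGCAAT")
        p1, t1 = simulate(seq, params, quick_mcmc.with_seed(4))
        p2, t2 = simulate(seq, params, quick_mcmc.with_seed(4))
        np.testing.assert_array_equal(p1.flip_prob, p2.flip_prob)
        np.testing.assert_array_equal(p1.mean_disp, p2.mean_disp)
        np.testing.assert_array_equal(t1.P, t2.P)

    def test_moment_scale_is_physical_displacement(self, params):
        # a 1-D chain's mean separation must match sqrt(2) * quadrature mean
        seq = DuplexSequence("s", "AA")
        cfg = MCMCConfig(preheat_sweeps=2000, production_sweeps=30000, seed=8)
        prof, _ = simulate(seq, params, cfg)
        assert np.all(prof.mean_sq_disp >= prof.mean_disp ** 2 - 1e-12)
        assert prof.mean_disp.max() < DISPLACEMENT_SCALE * cfg.y_max

    def test_edge_positions_have_no_long_bubbles(self, params, quick_mcmc):
        seq = DuplexSequence("s", "ATATATATAT")
        _, tens = simulate(seq, params, quick_mcmc)
        # a length-5 bubble cannot start within 4 bp of the right end
        li = list(tens.length_grid).index(5)
        assert np.all(tens.P[-4:, li, :] == 0.0)

    def test_threshold_lookup_warns_off_grid(self, params, quick_mcmc):
        seq = DuplexSequence("s", "ACGTACGT")
        prof, _ = simulate(seq, params, quick_mcmc)
        with pytest.warns(UserWarning):
            prof.flip_at(0.33)
        np.testing.assert_array_equal(
            prof.flip_at(FLIP_THRESHOLD), prof.flip_prob[:, 1]
        )


class TestBoltzmannDensity:
    def test_single_site_matches_1d_boltzmann(self, params):
        """KS check of the sampled 1-bp marginal against direct 1-D quadrature."""
        import scipy.stats as sps

        seq = DuplexSequence("s", "AA")
        # isolate one site by clamping the chain to a single base pair:
        # a 1-bp chain is not allowed, so use an uncoupled 2-mer instead
        p = EPBDParams(k_stack=1e-12, rho=0.0)
        cfg = MCMCConfig(proposal_sigma=2.0)
        rng = np.random.default_rng(17)
        state = DisplacementState(np.zeros(2))
        for _ in range(2000):  # burn-in
            state, _ = mcmc_sweep(state, seq, p, cfg, rng)
        samples = np.empty(10000)
        for k in range(samples.size):
            for _ in range(10):  # thin
                state, _ = mcmc_sweep(state, seq, p, cfg, rng)
            samples[k] = state.y[0]
        ys = np.linspace(cfg.y_min, cfg.y_max, 2001)
        dens = np.exp(-np.array([onsite_energy(v, "A", p) for v in ys]) / p.kT)
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(ys))])
        cdf /= cdf[-1]
        stat = sps.ks_1samp(samples, lambda q: np.interp(q, ys, cdf)).statistic
        assert stat < 0.05


class TestOracle:
    def test_trivial_thresholds(self, params):
        seq = DuplexSequence("s", "AT")
        cfg = MCMCConfig()
        high = oracle_expectation(seq, params, threshold=DISPLACEMENT_SCALE * cfg.y_max + 1)
        low = oracle_expectation(seq, params, threshold=DISPLACEMENT_SCALE * cfg.y_min - 1)
        np.testing.assert_allclose(high, 0.0, atol=1e-12)
        np.testing.assert_allclose(low, 1.0, atol=1e-12)

    def test_rejects_long_sequences(self, params):
        with pytest.raises(ValueError):
            oracle_expectation(DuplexSequence("s", "ATATATA"), params)

    def test_against_independent_adaptive_quadrature(self, params):
        """N=2 transfer-sum vs scipy adaptive 2-D quadrature (independent scheme)."""
        from scipy.integrate import dblquad

        seq = DuplexSequence("s", "AT")
        thr = 2.0
        thr_y = thr / DISPLACEMENT_SCALE
        kT = params.kT

        def density(y0, y1):
            e = (
                onsite_energy(y0, "A", params)
                + onsite_energy(y1, "T", params)
                + stacking_energy(y1, y0, "AT", params)
            )
            return math.exp(-e / kT)

        cfg = MCMCConfig()
        lo, hi = cfg.y_min, cfg.y_max
        total, _ = dblquad(density, lo, hi, lo, hi, epsabs=1e-10)
        above, _ = dblquad(density, thr_y, hi, lo, hi, epsabs=1e-10)  # y0 > thr
        expected = above / total
        got = oracle_expectation(seq, params, threshold=thr, check_convergence=True)
        assert got[0] == pytest.approx(expected, abs=1e-4)

    def test_mcmc_matches_oracle_on_short_duplex(self, params):
        """AATT at the documented test profile, 5 seeds, within 3 MC SEs."""
        seq = DuplexSequence("s", "AATT")
        orc = oracle_expectation(seq, params, threshold=FLIP_THRESHOLD)
        runs = []
        for sd in range(5):
            cfg = MCMCConfig(preheat_sweeps=2000, production_sweeps=20000, seed=sd)
            prof, _ = simulate(
                seq, params, cfg, threshold_grid=np.array([FLIP_THRESHOLD]),
                length_grid=np.array([1]),
            )
            runs.append(prof.flip_prob[:, 0])
        runs = np.array(runs)
        se = runs.std(axis=0, ddof=1) / np.sqrt(len(runs))
        assert np.all(np.abs(runs.mean(axis=0) - orc) <= 3 * np.maximum(se, 1e-3))
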