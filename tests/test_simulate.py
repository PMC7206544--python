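"""Kinetics, signal assembly and series planning."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from trxsim.noise_model import BeamParameters, synthetic_sigma
from trxsim.simulate import (
    KineticScheme,
    SimulationPlan,
    plan_report,
    populations_at,
    simulate_components,
    simulate_difference,
    simulate_series,
)
from trxsim.structures import MolecularStructure


@pytest.fixture(scope="module")
def chi3_scheme(chi3, chi2i, radical_pair):
    return KineticScheme(
        species={
            "reactant": (chi3,),
            "isomer": (chi2i,),
            "radical": radical_pair,
        },
        ground="reactant",
        initial_populations={"isomer": 0.4, "radical": 0.6},
        rates={("isomer", "reactant"): 3.3e6, ("radical", "reactant"): 2.0e5},
        excitation_fraction=0.3,
    )


@pytest.fixture(scope="module")
def beam():
    return BeamParameters(1e3, 1.5, 5e8, t=36.0, d=1.0)


@pytest.fixture(scope="module")
def noise_ref(q_full):
    return synthetic_sigma(0.5, q_full, beam=BeamParameters(1e3, 1.5, 5e8))


class TestPopulations:
    def test_negative_delay_all_ground(self, chi3_scheme):
        pops = populations_at(chi3_scheme, -3e-9)
        assert pops["reactant"] == 1.0
        assert pops["isomer"] == 0.0 and pops["radical"] == 0.0

    def test_prompt_branching_fractions(self, chi3_scheme):
        pops = populations_at(chi3_scheme, 0.0)
        assert pops["isomer"] == pytest.approx(0.4)
        assert pops["radical"] == pytest.approx(0.6)

    def test_single_decay_closed_form(self, chi3, chi2i):
        k = 1e7
        scheme = KineticScheme(
            species={"a": (chi2i,), "reactant": (chi3,)},
            ground="reactant",
            initial_populations={"a": 1.0},
            rates={("a", "reactant"): k},
            excitation_fraction=0.1,
        )
        t = 1.0 / k
        pops = populations_at(scheme, t)
        assert pops["a"] == pytest.approx(np.exp(-1.0), abs=1e-12)
        assert pops["reactant"] == pytest.approx(1 - np.exp(-1.0), abs=1e-12)

    def test_three_species_chain_matches_ode_oracle(self, chi3, chi2i, radical_pair):
        k1, k2 = 4.0e6, 7.5e5
        scheme = KineticScheme(
            species={"a": (chi2i,), "b": radical_pair, "reactant": (chi3,)},
            ground="reactant",
            initial_populations={"a": 1.0},
            rates={("a", "b"): k1, ("b", "reactant"): k2},
            excitation_fraction=0.1,
        )

        def rhs(_, y):
            a, b, g = y
            return [-k1 * a, k1 * a - k2 * b, k2 * b]

        for t in (1e-8, 3e-7, 2e-6):
            sol = solve_ivp(rhs, (0, t), [1.0, 0.0, 0.0], rtol=1e-12, atol=1e-14,
                            dense_output=True)
            expected = sol.y[:, -1]
            pops = populations_at(scheme, t)
            got = np.array([pops["a"], pops["b"], pops["reactant"]])
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_population_conservation_over_delays(self, chi3_scheme):
        for t in np.geomspace(1e-12, 1e-4, 25):
            total = sum(populations_at(chi3_scheme, t).values())
            assert abs(total - 1.0) < 1e-10

    def test_negative_rate_rejected(self, chi3, chi2i):
        with pytest.raises(ValueError):
            KineticScheme(
                species={"a": (chi2i,), "reactant": (chi3,)},
                ground="reactant", initial_populations={"a": 1.0},
                rates={("a", "reactant"): -1.0}, excitation_fraction=0.1,
            )


class TestSimulateDifference:
    def test_unexcited_system_noise_off_is_zero(self, chi3, cyclohexane, q_full,
                                                beam, noise_ref):
        scheme = KineticScheme(
            species={"reactant": (chi3,)}, ground="reactant",
            initial_populations={}, excitation_fraction=0.0,
        )
        curve = simulate_difference(
            scheme, cyclohexane, 0.01, beam, noise_ref, 100e-12, q_full, noise=False,
        )
        np.testing.assert_allclose(curve.intensity, 0.0, atol=1e-15)

    def test_noise_off_equals_component_sum(self, chi3_scheme, cyclohexane,
                                            q_full, beam, noise_ref):
        comps = simulate_components(
            chi3_scheme, cyclohexane, 0.01, 100e-12, q_full, r_heat=0.3
        )
        total = simulate_difference(
            chi3_scheme, cyclohexane, 0.01, beam, noise_ref, 100e-12, q_full,
            noise=False, r_heat=0.3,
        )
        expected = sum(c.intensity for c in comps.values())
        np.testing.assert_allclose(total.intensity, expected, atol=1e-12)

    def test_seeded_noise_is_reproducible(self, chi3_scheme, cyclohexane, q_full,
                                          beam, noise_ref):
        kwargs = dict(noise=True, seed=99, r_heat=0.3)
        a = simulate_difference(chi3_scheme, cyclohexane, 0.01, beam, noise_ref,
                                100e-12, q_full, **kwargs)
        b = simulate_difference(chi3_scheme, cyclohexane, 0.01, beam, noise_ref,
                                100e-12, q_full, **kwargs)
        assert np.array_equal(a.intensity, b.intensity)

    def test_noise_residual_std_matches_prediction(self, chi3_scheme, cyclohexane,
                                                   q_full, beam, noise_ref):
        """Residual of a noisy run vs the clean run has std sigma_target/sqrt(I)."""
        clean = simulate_difference(chi3_scheme, cyclohexane, 0.01, beam, noise_ref,
                                    100e-12, q_full, noise=False, r_heat=0.3)
        noisy = simulate_difference(chi3_scheme, cyclohexane, 0.01, beam, noise_ref,
                                    100e-12, q_full, noise=True, seed=5, r_heat=0.3)
        residual = noisy.intensity - clean.intensity
        # normalise per-point by the attached sigma, pooled std should be ~1
        z = residual / noisy.sigma
        assert np.std(z) == pytest.approx(1.0, rel=0.10)

    def test_noise_requires_seed(self, chi3_scheme, cyclohexane, q_full, beam,
                                 noise_ref):
        with pytest.raises(ValueError, match="seed"):
            simulate_difference(chi3_scheme, cyclohexane, 0.01, beam, noise_ref,
                                100e-12, q_full, noise=True)


class TestSeriesAndPlan:
    def make_plan(self, q, noise_ref, delays, total_time=86400.0, duty=0.7, seed=11):
        return SimulationPlan(
            delays=tuple(delays), total_time=total_time, duty_cycle=duty,
            beam=BeamParameters(1e3, 1.5, 5e8), noise_ref=noise_ref, seed=seed,
        )

    def test_one_curve_per_delay(self, chi3_scheme, cyclohexane, q_full, noise_ref):
        delays = [-3e-9, 100e-12, 30e-9, 1e-6]
        plan = self.make_plan(q_full, noise_ref, delays)
        result = simulate_series(plan, chi3_scheme, cyclohexane, 0.01, q_full,
                                 r_heat=0.3)
        assert len(result.curves) == len(delays)
        report = plan_report(plan, result)
        assert len(report) == len(delays)

    def test_negative_reference_delay_is_noise_only(self, chi3_scheme, cyclohexane,
                                                    q_full, noise_ref):
        plan = self.make_plan(q_full, noise_ref, [-3e-9, 100e-12])
        result = simulate_series(plan, chi3_scheme, cyclohexane, 0.01, q_full,
                                 r_heat=0.3)
        neg = result.curves[0].intensity
        clean_neg = result.noise_free[0].intensity
        assert np.all(clean_neg == 0.0)
        # the noisy negative-delay curve scatters around zero at the noise level
        sigma_avg = result.sigma_per_curve.intensity / np.sqrt(
            result.n_curves_per_delay
        )
        assert np.std(neg / sigma_avg) == pytest.approx(1.0, rel=0.15)

    def test_delay_count_noise_tradeoff(self, chi3_scheme, cyclohexane, q_full,
                                        noise_ref):
        """Splitting the same beam time over 40x more delays raises the
        per-delay averaged noise by sqrt(40)."""
        few = self.make_plan(q_full, noise_ref, np.linspace(1e-11, 1e-6, 10))
        many = self.make_plan(q_full, noise_ref, np.linspace(1e-11, 1e-6, 400))
        r_few = simulate_series(few, chi3_scheme, cyclohexane, 0.01, q_full,
                                noise=False, r_heat=0.3)
        r_many = simulate_series(many, chi3_scheme, cyclohexane, 0.01, q_full,
                                 noise=False, r_heat=0.3)
        ratio = np.sqrt(r_few.n_curves_per_delay / r_many.n_curves_per_delay)
        assert ratio == pytest.approx(np.sqrt(40), rel=0.01)

    def test_doubling_beam_time_shrinks_noise_sqrt2(self, chi3_scheme, cyclohexane,
                                                    q_full, noise_ref):
        base = self.make_plan(q_full, noise_ref, [100e-12], total_time=3600.0)
        double = self.make_plan(q_full, noise_ref, [100e-12], total_time=7200.0)
        r1 = simulate_series(base, chi3_scheme, cyclohexane, 0.01, q_full,
                             r_heat=0.3)
        r2 = simulate_series(double, chi3_scheme, cyclohexane, 0.01, q_full,
                             r_heat=0.3)
        assert r2.n_curves_per_delay == 2 * r1.n_curves_per_delay
        rep1 = plan_report(base, r1)
        rep2 = plan_report(double, r2)
        assert rep2.sigma_avg[0] == pytest.approx(
            rep1.sigma_avg[0] / np.sqrt(2), rel=1e-6
        )

    def test_snr_monotone_in_delay_count(self, chi3_scheme, cyclohexane, q_full,
                                         noise_ref):
        snrs = []
        for m in (10, 50, 250):
            plan = self.make_plan(q_full, noise_ref, np.linspace(1e-11, 1e-6, m))
            result = simulate_series(plan, chi3_scheme, cyclohexane, 0.01, q_full,
                                     noise=False, r_heat=0.3)
            # force the noise bookkeeping on for the report
            result = type(result)(
                delays=result.delays, curves=result.curves,
                noise_free=result.noise_free,
                n_curves_per_delay=result.n_curves_per_delay,
                sigma_per_curve=result.sigma_per_curve, noise_enabled=True,
            )
            snrs.append(plan_report(plan, result).snr.iloc[1])
        assert snrs[0] > snrs[1] > snrs[2]

    def test_noise_off_reports_sentinel_snr(self, chi3_scheme, cyclohexane, q_full,
                                            noise_ref):
        plan = self.make_plan(q_full, noise_ref, [100e-12])
        result = simulate_series(plan, chi3_scheme, cyclohexane, 0.01, q_full,
                                 noise=False, r_heat=0.3)
        report = plan_report(plan, result)
        assert np.isinf(report.snr[0])

    def test_allocation_without_pulse_pairs_rejected(self, chi3_scheme, cyclohexane,
                                                     q_full, noise_ref):
        plan = SimulationPlan(
            delays=(100e-12, 1e-9), total_time=1e-3, duty_cycle=1.0,
            beam=BeamParameters(1e3, 1.5, 5e8), noise_ref=noise_ref, seed=1,
        )
        with pytest.raises(ValueError, match="difference curves"):
            simulate_series(plan, chi3_scheme, cyclohexane, 0.01, q_full,
                            r_heat=0.3)

    def test_series_reproducible_from_plan_seed(self, chi3_scheme, cyclohexane,
                                                q_full, noise_ref):
        plan = self.make_plan(q_full, noise_ref, [100e-12, 30e-9], seed=77)
        a = simulate_series(plan, chi3_scheme, cyclohexane, 0.01, q_full, r_heat=0.3)
        b = simulate_series(plan, chi3_scheme, cyclohexane, 0.01, q_full, r_heat=0.3)
        for ca, cb in zip(a.curves, b.curves):
            assert np.array_equal(ca.intensity, cb.intensity)
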