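"""Speciation solver, signal model, and affinity fitting."""

import numpy as np
import pytest
from scipy.optimize import brentq

import popswitch as ps


def _oracle_free_metal(system):
    """Independent scalar root-finder on the mass-balance equation."""
    totals, kds = system.site_classes()

    def g(m):
        return m + np.sum(totals * m / (kds + m)) - system.metal_total

    if system.metal_total == 0:
        return 0.0
    return brentq(g, 0.0, system.metal_total, xtol=1e-300, rtol=8.9e-16)


class TestSpeciation:
    def test_stoichiometric_limit(self):
        sys_ = ps.EquilibriumSystem(metal_total=100.0, chelator_total=1e6,
                                    kd_chelator=1.0, protein_total=0.0)
        spec = ps.solve_speciation(sys_)
        assert spec.bound_chelator == pytest.approx(100.0, rel=1e-3)

    def test_symmetric_partitioning(self):
        sys_ = ps.EquilibriumSystem(metal_total=200.0, chelator_total=500.0,
                                    protein_total=500.0, kd_chelator=80.0,
                                    kd_protein=80.0)
        spec = ps.solve_speciation(sys_)
        assert spec.bound_chelator == pytest.approx(spec.bound_protein,
                                                    rel=1e-12)

    def test_matches_grid_oracle_single_case(self):
        sys_ = ps.EquilibriumSystem(metal_total=100.0, chelator_total=500.0,
                                    kd_chelator=200.0, protein_total=500.0,
                                    kd_protein=50.0)
        spec = ps.solve_speciation(sys_)
        m_ref = _oracle_free_metal(sys_)
        assert spec.free_metal == pytest.approx(m_ref, rel=1e-6)

    def test_matches_oracle_on_random_systems(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            sys_ = ps.EquilibriumSystem(
                metal_total=10 ** rng.uniform(-1, 4),
                chelator_total=10 ** rng.uniform(-1, 4),
                protein_total=10 ** rng.uniform(-1, 4),
                kd_chelator=10 ** rng.uniform(-1, 4),
                kd_protein=10 ** rng.uniform(-1, 4))
            spec = ps.solve_speciation(sys_)
            assert spec.free_metal == pytest.approx(
                _oracle_free_metal(sys_), rel=1e-6)

    def test_mass_conservation(self):
        sys_ = ps.EquilibriumSystem(metal_total=750.0, chelator_total=300.0,
                                    protein_total=400.0, kd_chelator=120.0,
                                    kd_protein=30.0, kd_nonspecific=66_000.0,
                                    nonspecific_sites=2)
        spec = ps.solve_speciation(sys_)
        total = (spec.free_metal + spec.bound_chelator + spec.bound_protein
                 + spec.nonspecific_bound)
        assert total == pytest.approx(750.0, rel=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ps.EquilibriumSystem(metal_total=-1.0)
        with pytest.raises(ValueError):
            ps.EquilibriumSystem(metal_total=0.0, kd_chelator=0.0)


class TestPredictSignal:
    def test_zero_metal_unquenched(self):
        sys_ = ps.EquilibriumSystem(metal_total=0.0, chelator_total=400.0,
                                    kd_chelator=100.0)
        resp = ps.ResponseModel(signal_free_chelator=2.0,
                                signal_bound_chelator=0.2, baseline=5.0)
        assert ps.predict_signal(sys_, resp) == pytest.approx(5.0 + 800.0)

    def test_saturation_limit(self):
        sys_ = ps.EquilibriumSystem(metal_total=1e9, chelator_total=400.0,
                                    kd_chelator=100.0)
        resp = ps.ResponseModel(signal_free_chelator=2.0,
                                signal_bound_chelator=0.2, baseline=5.0)
        assert ps.predict_signal(sys_, resp) == pytest.approx(5.0 + 80.0,
                                                              rel=1e-4)

    def test_mid_titration_matches_oracle(self):
        sys_ = ps.EquilibriumSystem(metal_total=300.0, chelator_total=500.0,
                                    protein_total=500.0, kd_chelator=100.0,
                                    kd_protein=41.5)
        resp = ps.ResponseModel()
        m = _oracle_free_metal(sys_)
        bound = 500.0 * m / (100.0 + m)
        expected = (resp.baseline
                    + resp.signal_free_chelator * (500.0 - bound)
                    + resp.signal_bound_chelator * bound)
        assert ps.predict_signal(sys_, resp) == pytest.approx(expected,
                                                              rel=1e-9)

    def test_quench_direction_enforced(self):
        with pytest.raises(ValueError):
            ps.ResponseModel(signal_free_chelator=0.1,
                             signal_bound_chelator=1.0)


class TestCompetitionFit:
    def test_noiseless_recovery_is_exact(self, competition_setup):
        cs = competition_setup
        series = ps.simulate_titration(cs["system"], cs["response"],
                                       cs["totals"], 3, 0.0, seed=0)
        fit = ps.fit_competition(series, 500.0, 500.0, 100.0, bootstrap_n=0)
        assert fit.kd_estimate == pytest.approx(41.5, rel=1e-4)
        assert fit.converged and not fit.pinned_at_bounds

    def test_noisy_recovery_within_bootstrap_ci(self, competition_setup):
        cs = competition_setup
        series = ps.simulate_titration(cs["system"], cs["response"],
                                       cs["totals"], 3, cs["noise_sd"],
                                       seed=12)
        fit = ps.fit_competition(series, 500.0, 500.0, 100.0,
                                 bootstrap_n=300, seed=1)
        lo, hi = fit.confidence_interval
        assert lo <= 41.5 <= hi
        assert lo <= fit.kd_estimate <= hi

    def test_recovery_sweep_small_median_bias(self, competition_setup):
        cs = competition_setup
        biases = []
        for kd_true in (10.0, 50.0, 250.0):
            sys_ = ps.EquilibriumSystem(metal_total=0.0, chelator_total=500.0,
                                        protein_total=500.0,
                                        kd_chelator=100.0,
                                        kd_protein=kd_true)
            rel = []
            for rep in range(30):
                series = ps.simulate_titration(sys_, cs["response"],
                                               cs["totals"], 3,
                                               cs["noise_sd"],
                                               seed=100 * rep + int(kd_true))
                fit = ps.fit_competition(series, 500.0, 500.0, 100.0,
                                         bootstrap_n=0)
                rel.append(fit.kd_estimate / kd_true - 1.0)
            biases.append(abs(np.median(rel)))
        assert max(biases) < 0.05

    def test_bootstrap_is_seeded(self, competition_setup):
        cs = competition_setup
        series = ps.simulate_titration(cs["system"], cs["response"],
                                       cs["totals"], 3, cs["noise_sd"],
                                       seed=5)
        f1 = ps.fit_competition(series, 500.0, 500.0, 100.0,
                                bootstrap_n=50, seed=7)
        f2 = ps.fit_competition(series, 500.0, 500.0, 100.0,
                                bootstrap_n=50, seed=7)
        assert f1.confidence_interval == f2.confidence_interval

    def test_tracer_chelator_leaves_protein_binding_unperturbed(self):
        """Apparent-affinity limit: a vanishing chelator concentration does
        not shift the protein's binding curve."""
        totals = np.linspace(0.0, 2000.0, 30)
        bound_with_tracer = []
        bound_alone = []
        for m in totals:
            with_tracer = ps.EquilibriumSystem(
                metal_total=m, chelator_total=0.01, protein_total=500.0,
                kd_chelator=100.0, kd_protein=50.0)
            alone = ps.EquilibriumSystem(
                metal_total=m, chelator_total=0.0, protein_total=500.0,
                kd_chelator=100.0, kd_protein=50.0)
            bound_with_tracer.append(
                ps.solve_speciation(with_tracer).bound_protein)
            bound_alone.append(ps.solve_speciation(alone).bound_protein)
        assert np.allclose(bound_with_tracer, bound_alone, rtol=1e-3,
                           atol=1e-6)


class TestDirectQuenchFit:
    def _direct_series(self, noise, seed, kd_chelator=100.0):
        sys_ = ps.EquilibriumSystem(metal_total=0.0, chelator_total=500.0,
                                    protein_total=0.0,
                                    kd_chelator=kd_chelator)
        totals = np.linspace(0.0, 2500.0, 16)
        return ps.simulate_titration(sys_, ps.ResponseModel(), totals, 3,
                                     noise, seed=seed)

    def test_noiseless_recovery_exact(self):
        fit = ps.fit_direct_quench(self._direct_series(0.0, 0), 500.0,
                                   bootstrap_n=0)
        assert fit.kd_estimate == pytest.approx(100.0, rel=1e-4)

    def test_noisy_recovery_within_ci(self):
        fit = ps.fit_direct_quench(self._direct_series(8.0, 3), 500.0,
                                   bootstrap_n=300, seed=2)
        lo, hi = fit.confidence_interval
        assert lo <= 100.0 <= hi

    def test_equivalent_to_competition_without_protein(self):
        """With no protein, the competition model collapses onto the direct
        quench model: fixing the chelator Kd at the direct estimate must
        reproduce the same fitted curves."""
        series = self._direct_series(5.0, 8)
        direct = ps.fit_direct_quench(series, 500.0, bootstrap_n=0)
        comp = ps.fit_competition(series, chelator_total=500.0,
                                  protein_total=0.0,
                                  kd_chelator=direct.kd_estimate,
                                  bootstrap_n=0)
        assert comp.residual_sd == pytest.approx(direct.residual_sd,
                                                 rel=1e-6)
        for rep in direct.nuisances:
            assert comp.nuisances[rep]["slope_free_chelator"] \
                == pytest.approx(
                    direct.nuisances[rep]["slope_free_chelator"], rel=1e-4)


class TestIsothermFit:
    def test_midpoint_without_depletion(self):
        f = ps.isotherm_fraction_bound([66.0], protein_total=1e-6, kd=66.0)
        assert f[0] == pytest.approx(0.5, abs=1e-4)

    def test_zero_metal_zero_fraction(self):
        assert ps.isotherm_fraction_bound([0.0], 100.0, 66.0)[0] == 0.0

    def test_noiseless_recovery(self):
        m = np.linspace(0.0, 500.0, 20)
        f = ps.isotherm_fraction_bound(m, protein_total=100.0, kd=66.0)
        fit = ps.fit_isotherm_depletion(100.0, m, f)
        assert fit.kd_estimate == pytest.approx(66.0, rel=1e-4)

    def test_noisy_recovery_within_ci(self):
        rng = np.random.default_rng(5)
        m = np.linspace(0.0, 500.0, 20)
        f = ps.isotherm_fraction_bound(m, 100.0, 66.0)
        noisy = np.clip(f + rng.normal(0, 0.02, f.size), 0, 1)
        fit = ps.fit_isotherm_depletion(100.0, m, noisy, bootstrap_n=200,
                                        seed=1)
        lo, hi = fit.confidence_interval
        assert lo <= 66.0 <= hi

    def test_fractions_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            ps.fit_isotherm_depletion(100.0, [10.0, 20.0], [0.5, 1.2])
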