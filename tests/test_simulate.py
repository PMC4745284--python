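"""Synthetic-data generator: Arrhenius forward model, noise, ledgers."""

import math

import numpy as np
import pytest

from thermokin import (
    SimulationScenario,
    build_ledger,
    fit_first_order,
    simulate_kd,
    simulate_ledger,
    simulate_study,
    simulate_timecourse,
)
from thermokin.constants import R, celsius_to_kelvin
from thermokin.errors import ValidationError
from thermokin.thermo import arrhenius_fit


class TestSimulateKd:
    def test_reference_identity(self):
        sc = SimulationScenario()
        assert simulate_kd(sc, sc.t_ref) == sc.kd_ref

    def test_zero_activation_energy_gives_flat_kd(self):
        sc = SimulationScenario(ea_true=0.0)
        kds = {simulate_kd(sc, t) for t in (80.0, 100.0, 120.0)}
        assert all(k == pytest.approx(sc.kd_ref, rel=1e-12) for k in kds)

    def test_closed_form_at_120c(self):
        """Default scenario (kd_ref = 46×10⁻⁴ at 80 °C, Ea = 31.102):
        independent closed-form evaluation at 120 °C."""
        sc = SimulationScenario()
        expected = 46e-4 * math.exp(
            -(31.102e3 / R) * (1 / celsius_to_kelvin(120.0) - 1 / celsius_to_kelvin(80.0))
        )
        assert expected == pytest.approx(0.013515, abs=1e-6)
        assert simulate_kd(sc, 120.0) == pytest.approx(expected, rel=1e-12)

    def test_kd_increases_with_temperature(self):
        sc = SimulationScenario()
        kds = [simulate_kd(sc, t) for t in sc.temperatures]
        assert all(a < b for a, b in zip(kds, kds[1:]))


class TestSimulateTimecourse:
    def test_noise_free_course_round_trips_kd(self):
        sc = SimulationScenario(noise_cv=0.0)
        fit = fit_first_order(simulate_timecourse(sc, 100.0))
        assert fit.kd == pytest.approx(simulate_kd(sc, 100.0), rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_same_seed_is_reproducible(self):
        sc = SimulationScenario(seed=42)
        a = simulate_timecourse(sc, 90.0)
        b = simulate_timecourse(sc, 90.0)
        assert a == b

    def test_different_seeds_differ(self):
        a = simulate_timecourse(SimulationScenario(seed=1), 90.0)
        b = simulate_timecourse(SimulationScenario(seed=2), 90.0)
        assert a != b

    def test_streams_split_per_condition(self):
        """Adding a condition never perturbs another condition's draws."""
        sc = SimulationScenario(
            seed=7, protection_factors={"mg": 0.8, "mannitol": 0.9}
        )
        control_alone = simulate_timecourse(sc, 80.0, "control")
        _ = simulate_timecourse(sc, 80.0, "mg")
        _ = simulate_timecourse(sc, 80.0, "mannitol")
        assert simulate_timecourse(sc, 80.0, "control") == control_alone

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValidationError, match="unknown condition"):
            simulate_timecourse(SimulationScenario(), 80.0, "EDTA")

    def test_protection_factor_calibrated_to_stabilizer_study(self):
        """A 150/180 protection factor applied to kd = ln2/150 at 80 °C
        yields a fitted half-life of 180 min — the magnesium+mannitol
        stabilization (150 → 180 min) of the reference lipase."""
        sc = SimulationScenario(
            kd_ref=math.log(2) / 150.0,
            noise_cv=0.0,
            protection_factors={"MgSO4 80 mM + mannitol 60 mM": 150.0 / 180.0},
        )
        fit = fit_first_order(
            simulate_timecourse(sc, 80.0, "MgSO4 80 mM + mannitol 60 mM")
        )
        assert fit.t_half == pytest.approx(180.0, rel=1e-9)

    def test_protection_factors_strictly_increase_half_life(self):
        sc = SimulationScenario(
            noise_cv=0.0, protection_factors={"stab": 0.6}
        )
        control = fit_first_order(simulate_timecourse(sc, 90.0, "control"))
        protected = fit_first_order(simulate_timecourse(sc, 90.0, "stab"))
        assert protected.t_half > control.t_half

    def test_lognormal_noise_has_requested_cv(self):
        """Empirical CV of the multiplicative noise matches noise_cv."""
        sc = SimulationScenario(
            noise_cv=0.1, time_grid=tuple(float(t) for t in range(0, 2000)),
            ea_true=0.0, kd_ref=1e-9, seed=3,
        )
        tc = simulate_timecourse(sc, 80.0)
        eps = np.asarray(tc.residuals) / 100.0  # decay is negligible
        assert eps.mean() == pytest.approx(1.0, abs=0.01)
        assert eps.std() == pytest.approx(0.1, rel=0.1)

    def test_gaussian_noise_option(self):
        sc = SimulationScenario(noise_model="gaussian", noise_cv=0.05, seed=5)
        tc = simulate_timecourse(sc, 80.0)
        assert all(r >= 0 for r in tc.residuals)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValidationError):
            SimulationScenario(kd_ref=0.0)
        with pytest.raises(ValidationError):
            SimulationScenario(noise_cv=-0.1)
        with pytest.raises(ValidationError):
            SimulationScenario(protection_factors={"bad": 0.0})


class TestEndToEndRecovery:
    def test_noise_free_pipeline_recovers_ea_exactly(self):
        sc = SimulationScenario(noise_cv=0.0)
        fits = [fit_first_order(tc) for tc in simulate_study(sc)]
        arr = arrhenius_fit([(f.temperature_c, f.kd) for f in fits])
        assert arr.ea == pytest.approx(sc.ea_true, rel=1e-9)
        for f in fits:
            assert f.t_half == pytest.approx(
                math.log(2) / simulate_kd(sc, f.temperature_c), rel=1e-9
            )

    def test_noisy_recovery_median_error_under_5pct(self):
        """100 seeded replicates at 2% noise, 7 points × 5 temperatures:
        median relative error of recovered Ea stays below 5%."""
        errors = []
        for seed in range(100):
            sc = SimulationScenario(noise_cv=0.02, seed=seed)
            fits = [fit_first_order(tc) for tc in simulate_study(sc)]
            arr = arrhenius_fit([(f.temperature_c, f.kd) for f in fits])
            errors.append(abs(arr.ea - sc.ea_true) / sc.ea_true)
        assert float(np.median(errors)) < 0.05


class TestSimulateLedger:
    def test_identity_trajectory(self):
        ledger = simulate_ledger(n_steps=3, step_recoveries=[1.0, 1.0],
                                 step_purities=[1.0, 1.0])
        for step in build_ledger(ledger):
            assert step.fold == pytest.approx(1.0)
            assert step.yield_pct == pytest.approx(100.0)

    def test_designed_trajectory_reproduced_exactly(self):
        """Construction-by-inversion: the final step is designed to give
        fold 12.15 and yield 1.98%, and the derivation returns exactly
        those numbers."""
        ledger = simulate_ledger(
            n_steps=4,
            step_recoveries=[0.0862, 3.83 / 8.62, 1.98 / 3.83],
            step_purities=[1.98, 4.67 / 1.98, 12.15 / 4.67],
        )
        steps = build_ledger(ledger)
        assert steps[-1].fold == pytest.approx(12.15, rel=1e-9)
        assert steps[-1].yield_pct == pytest.approx(1.98, rel=1e-9)

    def test_crude_only_ledger(self):
        ledger = simulate_ledger(n_steps=1, step_recoveries=[], step_purities=[])
        assert len(ledger) == 1

    def test_random_trajectory_is_seeded(self):
        assert simulate_ledger(seed=11) == simulate_ledger(seed=11)
        assert simulate_ledger(seed=11) != simulate_ledger(seed=12)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValidationError, match="recoveries"):
            simulate_ledger(n_steps=2, step_recoveries=[1.5], step_purities=[2.0])
        with pytest.raises(ValidationError, match="purity"):
            simulate_ledger(n_steps=2, step_recoveries=[0.5], step_purities=[0.5])
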