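"""MAS echo density-matrix simulation and Solomon cross-relaxation check."""

import numpy as np
import pytest

from poredyn.constants import default_context
from poredyn.relaxation import MotionModel, model_rate, DipolarPair
from poredyn.spinsim import (EchoProtocol, SpinSystem, bound_scaling_factor,
                             default_four_spin_system, echo_decay_time,
                             mas_dipolar_coefficient, powder_orientations,
                             propagate_echo, solomon_recovery, solomon_rates)
from poredyn.spinsim import _EchoEngine

CTX = default_context()
NU_R = 1200.0


def small_protocol(n_orient=16, steps=100, nu_r=NU_R):
    return EchoProtocol(nu_r=nu_r, steps_per_period=steps,
                        orientations=powder_orientations(n_orient))


class TestMasCoefficient:
    def test_zero_average_over_rotor_period(self, rng):
        """At the magic angle the secular coefficient integrates to zero
        over one full rotor period for any orientation."""
        t = np.linspace(0, 1 / NU_R, 20001)
        for _ in range(10):
            u = rng.normal(size=3)
            euler = rng.uniform(0, 2 * np.pi, 3)
            f = mas_dipolar_coefficient(u, euler, t, NU_R)
            avg = np.trapezoid(f, t) * NU_R
            assert abs(avg) < 1e-12

    def test_vector_along_rotor_axis_vanishes(self):
        t = np.linspace(0, 1 / NU_R, 100)
        f = mas_dipolar_coefficient([0, 0, 1.0], (0.0, 0.0, 0.0), t, NU_R)
        assert np.allclose(f, 0.0, atol=1e-14)

    def test_second_moment_independent_of_spinning_rate(self, rng):
        """Parseval: the time-average of the squared coefficient depends only
        on geometry, not on the MAS frequency."""
        u = rng.normal(size=3)
        euler = rng.uniform(0, 2 * np.pi, 3)
        moments = []
        for nu_r in (500.0, 5000.0, 50000.0):
            t = np.linspace(0, 1 / nu_r, 40001)
            f = mas_dipolar_coefficient(u, euler, t, nu_r)
            moments.append(np.trapezoid(f * f, t) * nu_r)
        assert np.ptp(moments) / np.mean(moments) < 1e-6


class TestEchoPropagation:
    def test_lambda_zero_echo_is_unity_with_shifts(self):
        """With all couplings scaled to zero, shifts are refocused by the
        pi pulse and the echo amplitude is exactly 1 for any n."""
        system = default_four_spin_system(lam=0.0,
                                          shifts_hz=[120.0, -340.0, 55.0, 900.0])
        prot = small_protocol(n_orient=4, steps=60)
        for n in (1, 3, 7):
            amp = propagate_echo(system, prot, n)
            assert abs(amp) == pytest.approx(1.0, abs=1e-10)
            assert amp.real == pytest.approx(1.0, abs=1e-10)

    def test_two_spin_full_period_echo_invariance(self, rng):
        """Two-spin secular dipolar Hamiltonian self-commutes; its net phase
        over full rotor periods is the (vanishing) coefficient integral, so
        the rotor-synchronized echo is 1 for any coupling strength."""
        prot = EchoProtocol(nu_r=NU_R, steps_per_period=120,
                            orientations=rng.uniform(0, 2 * np.pi, (50, 3)))
        for lam in (0.3, 1.0):
            system = SpinSystem(coords_nm=np.array([[0, 0, 0], [0.1, 0.12, 0.06]]),
                                lam=lam)
            amp = propagate_echo(system, prot, 2)
            assert abs(amp) == pytest.approx(1.0, abs=1e-9)

    def test_unitarity_of_propagation(self):
        """Coherent propagation conserves the density-matrix trace and
        Frobenius norm."""
        system = default_four_spin_system(lam=0.5, shifts_hz=[50, -20, 10, 80])
        engine = _EchoEngine(system, small_protocol(n_orient=1, steps=80))
        euler = engine.protocol.orientations[0]
        u = engine.period_propagator(euler)
        rho = engine.rho0
        rho_t = u @ rho @ u.conj().T
        assert np.trace(rho_t) == pytest.approx(np.trace(rho), abs=1e-10)
        assert np.linalg.norm(rho_t) == pytest.approx(np.linalg.norm(rho),
                                                      rel=1e-10)
        assert np.allclose(u @ u.conj().T, np.eye(engine.dim), atol=1e-10)

    def test_four_spin_decay_monotone(self):
        """At a coupling scale where the decay is resolved on the sampled
        rotor-period grid, the powder-averaged amplitude falls monotonically."""
        system = default_four_spin_system(lam=0.04)
        res = echo_decay_time(system, small_protocol(n_orient=34),
                              [0, 1, 2, 3, 4, 6, 8])
        assert np.all(np.diff(res.amplitudes) < 0)

    def test_t2_monotone_in_coupling_scale(self):
        """Halving every coupling lengthens the echo decay time."""
        prot = small_protocol(n_orient=34)
        n_list = [0, 1, 2, 3, 4, 6, 8]
        t2_full = echo_decay_time(default_four_spin_system(lam=0.04), prot,
                                  n_list).t2
        t2_half = echo_decay_time(default_four_spin_system(lam=0.02), prot,
                                  n_list).t2
        assert t2_half > t2_full

    def test_convergence_under_doubling(self):
        """Doubling the step count and the powder size changes the 4-spin
        echo amplitudes by < 1%."""
        n_list = [0, 2, 4, 6]
        base = echo_decay_time(default_four_spin_system(lam=0.04),
                               small_protocol(n_orient=72, steps=100), n_list)
        fine = echo_decay_time(default_four_spin_system(lam=0.04),
                               small_protocol(n_orient=144, steps=200), n_list)
        assert np.all(np.abs(base.amplitudes - fine.amplitudes) < 0.01)
        assert fine.t2 == pytest.approx(base.t2, rel=0.05)

    def test_spin_count_bounds(self):
        with pytest.raises(ValueError, match="spin count"):
            SpinSystem(coords_nm=np.zeros((1, 3)))
        with pytest.raises(ValueError, match="lam"):
            default_four_spin_system(lam=1.5)


class TestEchoDecayTime:
    def test_lambda_zero_flagged_non_decaying(self):
        res = echo_decay_time(default_four_spin_system(lam=0.0),
                              small_protocol(n_orient=4, steps=60),
                              [0, 1, 2, 3])
        assert res.non_decaying and res.t2 is None

    def test_needs_four_points(self):
        with pytest.raises(ValueError, match="4 echo points"):
            echo_decay_time(default_four_spin_system(lam=0.1),
                            small_protocol(n_orient=4), [0, 1, 2])


class TestBoundScalingFactor:
    @staticmethod
    def _factories():
        return (lambda lam: default_four_spin_system(lam=lam),
                lambda nu_r: small_protocol(n_orient=16, steps=100, nu_r=nu_r))

    def test_round_trip_reduction_factor(self):
        """A measurement equal to the simulation at lambda=0.02 yields a
        ~50-fold coupling-reduction bound."""
        sys_f, prot_f = self._factories()
        n_list = [0, 1, 2, 3, 4, 6, 8]
        t2_ref = echo_decay_time(sys_f(0.02), prot_f(NU_R), n_list).t2
        out = bound_scaling_factor([(NU_R, t2_ref)], sys_f, prot_f, n_list)
        assert out["reduction_factor"] == pytest.approx(50.0, rel=0.10)

    def test_smaller_lambda_recovers_larger_bound(self):
        # slower decay needs a longer echo train to resolve
        sys_f, prot_f = self._factories()
        n_list = [0, 2, 4, 8, 12, 16, 24]
        t2_ref = echo_decay_time(sys_f(0.01), prot_f(NU_R), n_list).t2
        out = bound_scaling_factor([(NU_R, t2_ref)], sys_f, prot_f, n_list)
        assert out["reduction_factor"] >= 50.0

    def test_rigid_limit_consistency(self):
        """A measured T2 slower than even the rigid-limit simulation leaves
        lambda unbounded above (bound = 1)."""
        sys_f, prot_f = self._factories()
        n_list = [0, 1, 2, 3]
        rigid = echo_decay_time(sys_f(1.0), prot_f(NU_R), n_list)
        t2_rigid = rigid.t2 if not rigid.non_decaying else np.inf
        out = bound_scaling_factor([(NU_R, t2_rigid * 0.5)], sys_f, prot_f,
                                   n_list)
        assert out["lambda_max"] == 1.0


class TestSolomon:
    MOTION = MotionModel(0.25, 50e-9, 1e-9)

    def test_cross_off_is_single_exponential_with_model_rate(self):
        """Decoupled 13C recovery is exp(-R1 t) with R1 from the rate model."""
        t = np.linspace(0, 3.0, 40)
        traj = solomon_recovery(self.MOTION, CTX, t, cross_on=False)
        pair = DipolarPair("13C", "1H", 0.110e-9)
        r1 = model_rate("R1", pair, self.MOTION, CTX)
        expected = 1.0 - 2.0 * np.exp(-r1 * t)
        assert np.allclose(traj["mz_c"], expected, atol=1e-10)

    def test_cross_relaxation_negligible_without_partner_pulse(self):
        """With 1H at equilibrium, cross-on and cross-off 13C recovery curves
        differ by < 2% of the recovery range."""
        t = np.linspace(0, 3.0, 300)
        on = solomon_recovery(self.MOTION, CTX, t, cross_on=True)
        off = solomon_recovery(self.MOTION, CTX, t, cross_on=False)
        diff = np.max(np.abs(on["mz_c"] - off["mz_c"])) / 2.0
        assert diff < 0.02

    def test_partner_pulse_alters_recovery(self):
        """Inverting 1H as well makes cross-relaxation clearly visible, and
        slows the apparent 13C recovery (positive cross rate at these taus)."""
        t = np.linspace(0, 3.0, 300)
        pulsed = solomon_recovery(self.MOTION, CTX, t, cross_on=True,
                                  partner_pulse=True)
        off = solomon_recovery(self.MOTION, CTX, t, cross_on=False,
                               partner_pulse=True)
        diff = np.max(np.abs(pulsed["mz_c"] - off["mz_c"])) / 2.0
        assert diff > 0.05
        _, _, sig = solomon_rates(self.MOTION, CTX)
        assert sig > 0
        # transient overshoot past equilibrium: the cross-relaxation signature
        assert np.max(pulsed["mz_c"]) > 1.02
        assert np.max(off["mz_c"]) <= 1.0 + 1e-9

    def test_auto_rates_positive(self):
        rho_h, rho_c, _ = solomon_rates(self.MOTION, CTX)
        assert rho_h > 0 and rho_c > 0
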