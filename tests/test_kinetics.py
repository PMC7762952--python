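"""Mechanism definitions, ODE integration, and relaxation-rate analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phimap as pm
from phimap.kinetics import SCHEME_NAMES


def _total_a(scheme_name, traj):
    if scheme_name == "two_state":
        return traj["A"] + traj["AB"]
    if scheme_name == "induced_fit":
        return traj["A"] + traj["AB"] + traj["ABx"]
    return traj["A"] + traj["AB"] + traj["AC"]


class TestSchemes:
    def test_species_and_rate_counts(self):
        assert pm.get_scheme("two_state").species == ("A", "B", "AB")
        assert len(pm.get_scheme("two_state").rate_symbols) == 2
        assert set(pm.get_scheme("induced_fit").species) == {"A", "B", "AB", "ABx"}
        assert len(pm.get_scheme("induced_fit").rate_symbols) == 4
        assert set(pm.get_scheme("displacement").species) == {"A", "B", "C", "AB", "AC"}
        assert len(pm.get_scheme("displacement").rate_symbols) == 4

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            pm.get_scheme("three_state")

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="must be >= 0"):
            pm.RateParameters(kon=30.0, koff=-1.0)

    def test_missing_rate_for_scheme(self):
        with pytest.raises(ValueError, match="requires rate"):
            pm.RateParameters(kon=30.0).for_scheme(pm.get_scheme("two_state"))


class TestIntegration:
    def test_two_state_equilibrium_matches_quadratic(self):
        """Long-time [AB] solves the closed-form equilibrium condition."""
        rates = pm.RateParameters(kon=30.4, koff=24.7)
        t = np.linspace(0, 2.0, 200)
        traj = pm.integrate_scheme(pm.get_scheme("two_state"), rates,
                                   {"A": 1.0, "B": 6.0}, t)
        Kd, A0, B0 = 24.7 / 30.4, 1.0, 6.0
        ab_eq = ((A0 + B0 + Kd) - np.sqrt((A0 + B0 + Kd) ** 2 - 4 * A0 * B0)) / 2
        assert traj["AB"][-1] == pytest.approx(ab_eq, rel=1e-6)
        # and the implied Kd from the final concentrations is koff/kon
        kd_out = traj["A"][-1] * traj["B"][-1] / traj["AB"][-1]
        assert kd_out == pytest.approx(Kd, rel=1e-5)

    def test_zero_initial_concentrations(self):
        rates = pm.RateParameters(kon=1.0, koff=1.0)
        traj = pm.integrate_scheme(pm.get_scheme("two_state"), rates, {},
                                   np.linspace(0, 1, 50))
        assert all(np.all(v == 0) for v in traj.values())

    def test_induced_fit_k2_zero_reduces_to_two_state(self):
        t = np.linspace(0, 0.3, 300)
        conc = {"A": 1.0, "B": 6.0}
        ifit = pm.integrate_scheme(
            pm.get_scheme("induced_fit"),
            pm.RateParameters(k1=30.4, kminus1=24.7, k2=0.0, kminus2=1.0),
            conc, t)
        ts = pm.integrate_scheme(
            pm.get_scheme("two_state"),
            pm.RateParameters(kon=30.4, koff=24.7), conc, t)
        assert np.all(ifit["ABx"] == pytest.approx(0.0, abs=1e-10))
        np.testing.assert_allclose(ifit["AB"], ts["AB"], rtol=1e-6, atol=1e-9)

    @given(
        k2=st.floats(0.5, 50), km2=st.floats(0.5, 50),
        kon=st.floats(1, 100), koff=st.floats(1, 200),
        a0=st.floats(0.1, 3), b0=st.floats(0.1, 20),
    )
    def test_mass_conservation(self, k2, km2, kon, koff, a0, b0):
        """Total A and total B are conserved to 1e-8 relative, all species >= 0."""
        rates = pm.RateParameters(kon=kon, koff=koff, k1=kon, kminus1=koff,
                                  k2=k2, kminus2=km2)
        t = np.linspace(0, 0.5, 60)
        for name in ("two_state", "induced_fit"):
            traj = pm.integrate_scheme(pm.get_scheme(name), rates,
                                       {"A": a0, "B": b0}, t)
            np.testing.assert_allclose(_total_a(name, traj), a0, rtol=1e-8)
            assert all(np.all(v >= 0) for v in traj.values())

    def test_displacement_conservation(self):
        rates = pm.RateParameters(kon=30.4, koff=24.7, k1=30.4, kminus1=1.0)
        t = np.linspace(0, 1.0, 100)
        traj = pm.integrate_scheme(pm.get_scheme("displacement"), rates,
                                   {"AB": 1.0, "C": 20.0}, t)
        np.testing.assert_allclose(traj["A"] + traj["AB"] + traj["AC"], 1.0,
                                   rtol=1e-8)
        np.testing.assert_allclose(traj["C"] + traj["AC"], 20.0, rtol=1e-8)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative initial concentration"):
            pm.integrate_scheme(pm.get_scheme("two_state"),
                                pm.RateParameters(kon=1, koff=1),
                                {"A": -1.0}, [0, 1])


class TestObserve:
    def _traj(self):
        return {"AB": np.array([0.0, 0.5, 1.0]), "A": np.array([1.0, 0.5, 0.0])}

    def test_zero_coefficients_gives_baseline(self):
        tr = pm.observe(self._traj(), pm.ObservableModel(baseline=2.0))
        assert np.all(tr.signal == 2.0)

    def test_complex_coefficient_returns_complex_trace(self):
        obs = pm.ObservableModel(baseline=0.0, species_coefficients={"AB": 1.0})
        tr = pm.observe(self._traj(), obs)
        np.testing.assert_array_equal(tr.signal, self._traj()["AB"])

    def test_scale_linearity(self):
        obs1 = pm.ObservableModel(baseline=1.0, species_coefficients={"AB": 2.0})
        obs2 = pm.ObservableModel(baseline=1.0, species_coefficients={"AB": 2.0},
                                  scale=1.15)
        t1 = pm.observe(self._traj(), obs1)
        t2 = pm.observe(self._traj(), obs2)
        np.testing.assert_allclose(t2.signal, 1.15 * t1.signal)

    def test_unknown_species_coefficient(self):
        obs = pm.ObservableModel(species_coefficients={"XY": 1.0})
        with pytest.raises(ValueError, match="unknown species"):
            pm.observe(self._traj(), obs)

    def test_scale_outside_band_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            pm.ObservableModel(scale=1.5)


class TestAnalyticKobs:
    def test_two_state_value(self):
        ks = pm.analytic_kobs(pm.get_scheme("two_state"),
                              pm.RateParameters(kon=30.4, koff=24.7), 6.0)
        assert ks == [pytest.approx(207.1)]

    def test_zero_ligand_gives_koff(self):
        ks = pm.analytic_kobs(pm.get_scheme("two_state"),
                              pm.RateParameters(kon=30.4, koff=24.7), 0.0)
        assert ks == [pytest.approx(24.7)]

    def test_two_state_matches_ode_relaxation(self):
        """The pseudo-first-order rate converges on the fitted ODE decay.

        Ligand depletion biases the observed rate low by roughly the
        bound fraction over the excess ratio, so the deviation shrinks
        monotonically with excess and is below 1% from 50-fold on.
        """
        rates = pm.RateParameters(kon=30.4, koff=24.7)
        scheme = pm.get_scheme("two_state")
        devs = []
        for B in (10.0, 20.0, 50.0, 100.0):
            kobs = pm.analytic_kobs(scheme, rates, B)[0]
            t = np.linspace(0.0, 5.0 / kobs, 400)
            traj = pm.integrate_scheme(scheme, rates, {"A": 1.0, "B": B}, t)
            fit = pm.fit_exponentials(pm.Trace(time=t, signal=traj["AB"]), 1)
            devs.append(abs(fit.phases[0].kobs / kobs - 1.0))
        assert devs == sorted(devs, reverse=True)
        assert devs[0] < 0.05
        assert all(d < 0.01 for d in devs[2:])

    @given(k1=st.floats(1, 100), km1=st.floats(1, 300),
           k2=st.floats(0.5, 50), km2=st.floats(0.5, 50),
           B=st.floats(0.0, 100))
    def test_induced_fit_trace_determinant_identity(self, k1, km1, k2, km2, B):
        """Eigenvalue pair satisfies the closed-form trace/determinant relations."""
        rates = pm.RateParameters(k1=k1, kminus1=km1, k2=k2, kminus2=km2)
        l1, l2 = pm.analytic_kobs(pm.get_scheme("induced_fit"), rates, B)
        assert l1 >= l2
        assert l1 + l2 == pytest.approx(k1 * B + km1 + k2 + km2, rel=1e-9)
        assert l1 * l2 == pytest.approx(k1 * B * (k2 + km2) + km1 * km2,
                                        rel=1e-6, abs=1e-9)

    def test_induced_fit_slow_phase_limit(self):
        """The concentration-independent slow phase tends to k2 + k-2."""
        rates = pm.RateParameters(k1=30.4, kminus1=146.0, k2=4.0, kminus2=12.0)
        scheme = pm.get_scheme("induced_fit")
        slow = [pm.analytic_kobs(scheme, rates, B)[1] for B in (1e3, 1e4, 1e5)]
        assert slow == sorted(slow)  # monotone approach
        assert slow[-1] == pytest.approx(16.0, rel=1e-3)

    def test_negative_ligand_rejected(self):
        with pytest.raises(ValueError):
            pm.analytic_kobs(pm.get_scheme("two_state"),
                             pm.RateParameters(kon=1, koff=1), -1.0)


class TestPreprocess:
    def test_shift_then_cutoff(self):
        t = np.linspace(0.0, 0.1, 101)  # 1 ms steps
        tr = pm.Trace(time=t, signal=np.ones_like(t))
        out = pm.preprocess(tr)
        # shift of +1.25 ms, then nothing before 2 ms survives
        assert out.time.min() >= 0.002
        assert out.time[0] == pytest.approx(0.00225)
        assert out.n_points < tr.n_points

    def test_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            pm.Trace(time=np.array([0.0, 0.0, 1.0]), signal=np.zeros(3))


class TestFitExponentials:
    def test_single_phase_roundtrip(self):
        t = np.linspace(0.002, 0.06, 500)
        y = 2.0 + 0.8 * np.exp(-100.0 * (t - t[0]))
        fit = pm.fit_exponentials(pm.Trace(time=t, signal=y), 1)
        assert fit.success
        assert fit.phases[0].kobs == pytest.approx(100.0, rel=1e-3)

    def test_double_phase_roundtrip(self):
        t = np.linspace(0.002, 0.4, 1000)
        y = 1.0 + 0.5 * np.exp(-200 * (t - t[0])) + 0.3 * np.exp(-16 * (t - t[0]))
        fit = pm.fit_exponentials(pm.Trace(time=t, signal=y), 2)
        assert fit.success
        ks = [p.kobs for p in fit.phases]
        assert ks[0] == pytest.approx(200.0, rel=1e-3)
        assert ks[1] == pytest.approx(16.0, rel=1e-3)
        assert ks[0] > ks[1]  # ordered descending

    def test_constant_signal_flagged_unidentifiable(self, rng):
        t = np.linspace(0.002, 0.1, 300)
        y = 1.0 + rng.normal(0, 1e-3, t.size)
        fit = pm.fit_exponentials(pm.Trace(time=t, signal=y), 1)
        phase = fit.phases[0]
        assert not phase.identifiable
        # realized signal change of the phase over the window is ~ 0
        change = abs(phase.amplitude) * (1 - np.exp(-phase.kobs * (t[-1] - t[0])))
        assert change < 3 * 1e-3

    def test_residuals_returned(self):
        t = np.linspace(0.002, 0.06, 200)
        y = 1.0 + 0.5 * np.exp(-50 * (t - t[0]))
        fit = pm.fit_exponentials(pm.Trace(time=t, signal=y), 1)
        assert fit.residuals.shape == t.shape
        assert np.max(np.abs(fit.residuals)) < 1e-8


class TestDisplacement:
    @pytest.mark.parametrize("koff", [24.7, 2.66])
    def test_koff_recovered_at_20x_excess(self, koff):
        """Displacement kobs at 20-fold competitor excess estimates koff within 5%."""
        spec = pm.TraceSpec(
            scheme="displacement",
            rates=pm.RateParameters(kon=30.4, koff=koff, k1=30.4, kminus1=1.0),
            ligand_series=(5.0, 10.0, 20.0, 30.0), n_points=400,
        )
        traces, _ = pm.make_traces(spec)
        pre = pm.TraceSet([pm.preprocess(t) for t in traces])
        est, se = pm.estimate_koff_displacement(pre)
        assert est == pytest.approx(koff, rel=0.05)

    def test_monotone_approach_to_koff(self):
        """kobs approaches koff from below as competitor excess grows."""
        rates = pm.RateParameters(kon=30.4, koff=24.7, k1=30.4, kminus1=1.0)
        scheme = pm.get_scheme("displacement")
        kobs = []
        for excess in (5.0, 20.0, 100.0, 500.0):
            t = np.linspace(0, 0.5, 500)
            traj = pm.integrate_scheme(scheme, rates, {"AB": 1.0, "C": excess}, t)
            fit = pm.fit_exponentials(pm.Trace(time=t[1:], signal=traj["AB"][1:]), 1)
            kobs.append(fit.phases[0].kobs)
        assert kobs == sorted(kobs)
        assert kobs[-1] == pytest.approx(24.7, rel=0.01)

    def test_no_qualifying_trace_raises(self):
        t = np.linspace(0.002, 0.1, 100)
        tr = pm.Trace(time=t, signal=np.ones_like(t),
                      concentrations={"AB": 1.0, "C": 0.0})
        with pytest.raises(ValueError, match="20-fold excess"):
            pm.estimate_koff_displacement(pm.TraceSet([tr]))
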