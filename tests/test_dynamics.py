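"""Integration, steady states, and the dynamical invariants of the network."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import root

from ibdqsp.dynamics import (SolverSettings, derivatives, make_rhs, simulate,
                             steady_state)
from ibdqsp.params import ParameterSet, nominal_parameters
from ibdqsp.population import default_priors
from ibdqsp.species import IDX, N_SPECIES, SPECIES

FAST = SolverSettings(rtol=1e-6, atol=1e-8)


def _zero_floor_params(nominal) -> ParameterSet:
    """All influx and basal-production floors set to zero."""
    vals = nominal.as_dict()
    for name in vals:
        if name.startswith(("s_", "b_")) and name not in (
                "b_DC", "b_M", "b_Neu", "b_NK", "b_IL6_TNF"):
            vals[name] = 0.0
    # activation floors are dimensionless fractions, also zeroed
    for name in ("b_DC", "b_M", "b_Neu", "b_NK", "b_IL6_TNF"):
        vals[name] = 0.0
    return ParameterSet(vals)


class TestDerivatives:
    def test_zero_state_with_zero_floors_is_absorbing(self, nominal):
        params = _zero_floor_params(nominal)
        rates = derivatives(np.zeros(N_SPECIES), params)
        assert np.all(rates == 0.0)

    def test_negative_state_rejected(self, nominal, design_vec):
        bad = design_vec.copy()
        bad[IDX["IL6"]] = -1.0
        with pytest.raises(ValueError):
            derivatives(bad, nominal)

    def test_tnf_blockade_leaves_tnf_independent_activation(self, nominal,
                                                            design_vec):
        """With TNFα fully bound, innate activation falls to its
        TNFα-independent level (floor plus the IFNγ / IL-17 / IL-6 inputs)."""
        d_blocked = derivatives(design_vec, nominal, {"TNFa": 0.0})

        def hill(x, km):
            return x / (km + x)

        y = {s: design_vec[IDX[s]] for s in SPECIES}
        r_dc = nominal["k_aDC"] * y["iDC"] * (
            nominal["b_DC"]
            + nominal["alpha_IL6_DC"] * hill(y["IL6"], nominal["Km_IL6_DC"]))
        r_m = nominal["k_aM"] * y["M0"] * (
            nominal["b_M"]
            + nominal["alpha_IFN_M"] * hill(y["IFNg"], nominal["Km_IFN_M"]))
        r_n = nominal["k_aN"] * y["Neu"] * (
            nominal["b_Neu"]
            + nominal["alpha_IL17_Neu"] * hill(y["IL17"], nominal["Km_IL17_Neu"]))
        assert d_blocked[IDX["eDC"]] == pytest.approx(
            r_dc - nominal["kd_eDC"] * y["eDC"], rel=1e-12)
        assert d_blocked[IDX["M1"]] == pytest.approx(
            r_m - nominal["kd_M1"] * y["M1"], rel=1e-12)
        assert d_blocked[IDX["Neu_a"]] == pytest.approx(
            r_n - nominal["kd_Neu_a"] * y["Neu_a"], rel=1e-12)

    def test_rates_match_finite_difference_of_trajectory(self, nominal,
                                                         design_vec):
        """d/dt from the RHS equals a centred finite difference of the
        integrated trajectory, to 1e-6 relative."""
        y0 = design_vec * 1.3  # off-equilibrium so rates are non-trivial
        h = 1e-4
        traj = simulate(nominal, 2 * h, grid=np.array([0.0, h, 2 * h]),
                        y0=y0)
        fd = (traj.states[2] - traj.states[0]) / (2 * h)
        an = derivatives(y0 := traj.states[1], nominal)
        scale = np.maximum(np.abs(an), 1e-6)
        assert np.max(np.abs(fd - an) / scale) < 1e-6


class TestSimulate:
    def test_steady_state_is_fixed_point_over_12_weeks(self, nominal):
        ss = steady_state(nominal)
        traj = simulate(nominal, 84.0, None, y0=ss.values)
        drift = np.abs(traj.states - ss.values) / (1.0 + np.abs(ss.values))
        assert drift.max() < 1e-4

    def test_il6_blockade_lowers_crp(self, nominal):
        ss = steady_state(nominal)
        traj = simulate(nominal, 84.0, lambda t: (1.0, 0.0, 1.0, 1.0),
                        y0=ss.values)
        assert traj.marker("CRP")[-1] < ss["CRP"]

    def test_endpoint_agrees_with_root_finder(self, nominal):
        """The long-horizon endpoint under constant partial TNFα blockade
        equals the algebraic root of the rate equations, to 1e-5."""
        ss = steady_state(nominal)
        ff = (0.3, 1.0, 1.0, 1.0)
        traj = simulate(nominal, 400.0, lambda t: ff, y0=ss.values,
                        grid=np.array([0.0, 400.0]))
        endpoint = traj.states[-1]
        rhs = make_rhs(nominal, lambda t, y: ff)
        sol = root(lambda v: np.asarray(rhs(0.0, v)), ss.values, method="hybr")
        assert sol.success
        assert np.max(np.abs(endpoint - sol.x) / (1.0 + np.abs(sol.x))) < 1e-5

    def test_invalid_grid_rejected(self, nominal, design_vec):
        with pytest.raises(ValueError):
            simulate(nominal, 10.0, grid=np.array([0.0, 11.0]), y0=design_vec)


class TestSteadyState:
    def test_zero_sources_give_zero_state(self, nominal):
        """With all influxes and basal floors at zero the only steady state
        is extinction of every population."""
        params = _zero_floor_params(nominal)
        ss = steady_state(params, tol=1e-10)
        assert np.max(np.abs(ss.values)) < 1e-6

    def test_matches_long_integration(self, nominal):
        params = nominal.perturbed({"p_IL6": 2.0, "kdeg_TNF": 0.5})
        ss = steady_state(params)
        traj = simulate(params, 2000.0, None, y0=ss.values * 1.5,
                        grid=np.array([0.0, 2000.0]), solver=FAST)
        assert np.max(np.abs(traj.states[-1] - ss.values)
                      / (1.0 + np.abs(ss.values))) < 1e-5

    def test_crp_increases_with_il6_gain(self, nominal):
        base = steady_state(nominal)
        doubled = steady_state(nominal.perturbed({"p_IL6": 2.0}))
        assert doubled["CRP"] > base["CRP"]


class TestInvariants:
    def test_non_negative_trajectories_across_sampled_patients(self, nominal):
        """Sampled parameter sets, random non-negative initial states:
        concentrations never go negative."""
        priors = default_priors()
        names = list(priors)
        rng = np.random.default_rng(5)
        los = np.log([priors[k][0] for k in names])
        his = np.log([priors[k][1] for k in names])
        from ibdqsp.params import design_state_vector

        for _ in range(12):
            factors = dict(zip(names, np.exp(rng.uniform(los, his))))
            params = nominal.perturbed(factors)
            y0 = rng.uniform(0.0, 2.0, N_SPECIES) * design_state_vector()
            traj = simulate(params, 30.0, None, y0=y0, solver=FAST)
            assert traj.states.min() >= 0.0

    def test_target_suppression_never_raises_crp(self, nominal):
        """Reducing any drug target's free fraction cannot raise steady CRP
        (50 sampled parameter sets, algebraic steady states)."""
        priors = default_priors()
        names = list(priors)
        rng = np.random.default_rng(9)
        los = np.log([priors[k][0] for k in names])
        his = np.log([priors[k][1] for k in names])
        checked = 0
        for _ in range(60):
            if checked >= 50:
                break
            factors = dict(zip(names, np.exp(rng.uniform(los, his))))
            params = nominal.perturbed(factors)
            try:
                base = steady_state(params, settle_days=300.0)
            except Exception:
                continue
            checked += 1
            target = ("TNFa", "IL6", "IL12", "IL23")[checked % 4]
            ff = tuple(0.5 if c == target else 1.0
                       for c in ("TNFa", "IL6", "IL12", "IL23"))
            rhs = make_rhs(params, lambda t, y, _f=ff: _f)
            sol = root(lambda v: np.asarray(rhs(0.0, v)), base.values,
                       method="hybr")
            if not sol.success:
                continue
            assert sol.x[IDX["CRP"]] <= base["CRP"] * (1.0 + 1e-6)
        assert checked >= 50
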