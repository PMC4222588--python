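import numpy as np
import pytest

import callusim as cs
from callusim.domain import FIELD_NAMES, StateFields
from callusim.pde import (transport_step, reaction_terms, oxygen_multipliers,
                          stability_limit, check_stability, Simulation)
from callusim.scenarios import toy_fixture
from naive_reference import naive_transport_step


def _zero_reaction_params(params):
    """All reaction rate constants zero: transport only."""
    from dataclasses import fields as dc_fields
    zeros = {}
    for f in dc_fields(params.reactions):
        if f.name in ("D_cm", "D_cf", "D_gbc", "D_gv", "chi_cm", "chi_cf",
                      "c_max", "m_max", "H_osteo", "H_chondro", "H_gn",
                      "c_gv_half"):
            continue
        zeros[f.name] = 0.0
    return params.with_overrides(reactions=zeros)


class TestTransport:
    def test_uniform_field_unchanged(self, conservation_box, desk_params):
        dom, st, _ = conservation_box
        for name in FIELD_NAMES:
            st[name] = np.full(dom.shape, 0.7)
        before = st.copy()
        transport_step(st, dom, None, 0.02, desk_params)
        for name in FIELD_NAMES:
            assert np.allclose(st[name], before[name], atol=1e-14)

    def test_no_flux_mass_conservation(self, conservation_box, desk_params):
        dom, st, _ = conservation_box
        m0 = {f: a.sum() for f, a in st.items()}
        for _ in range(200):
            transport_step(st, dom, None, 0.02, desk_params)
        for f in ("cm", "cf", "gbc", "gv", "n"):
            assert abs(st[f].sum() - m0[f]) <= 1e-8 * m0[f]

    def test_matches_naive_reference(self, conservation_box, desk_params):
        dom, st, _ = conservation_box
        st.gbc = st.gbc + 0.5 * np.random.default_rng(0).random(dom.shape)
        ref = st.copy()
        for _ in range(10):
            transport_step(st, dom, None, 0.02, desk_params)
            naive_transport_step(ref, dom, 0.02, desk_params)
        for name in ("cm", "cf", "gbc", "gv", "n"):
            assert np.abs(st[name] - ref[name]).max() < 1e-10

    def test_gaussian_spread_matches_diffusion_kernel(self):
        # point release far from boundaries: variance grows as 2 D t
        from callusim.scenarios import _toy_domain
        dom = _toy_domain(31, 31, 0.1)
        st = StateFields.zeros(dom)
        st.gv[15, 15] = 1.0
        p = cs.desk_profile().with_overrides(reactions={"d_gv": 0.0})
        D = p.reactions.D_gv
        dt = 0.005
        nsteps = 60
        for _ in range(nsteps):
            transport_step(st, dom, None, dt, p)
        X = np.broadcast_to(dom.x_centers, dom.shape)
        total = st.gv.sum()
        mean = (st.gv * X).sum() / total
        var = (st.gv * (X - mean) ** 2).sum() / total
        expected = 2 * D * nsteps * dt + dom.dx ** 2 / 12  # + cell width
        assert var == pytest.approx(expected, rel=0.05)

    def test_stability_violation_aborts(self, desk_params):
        dt_bad = 2 * stability_limit(desk_params)
        with pytest.raises(RuntimeError):
            check_stability(desk_params, dt_bad)

    def test_semi_implicit_conserves_and_agrees(self, conservation_box):
        dom, st, _ = conservation_box
        p_exp = cs.desk_profile()
        p_imp = p_exp.with_overrides(solver={"semi_implicit_diffusion": True})
        st2 = st.copy()
        m0 = st.n.sum()
        for _ in range(50):
            transport_step(st, dom, None, 0.02, p_exp)
            transport_step(st2, dom, None, 0.02, p_imp)
        assert abs(st2.n.sum() - m0) <= 1e-10 * m0
        assert np.abs(st.n - st2.n).max() < 1e-2


class TestReactions:
    def test_zero_state_zero_rates(self, conservation_box, desk_params):
        dom, _, _ = conservation_box
        st = StateFields.zeros(dom)
        mods = oxygen_multipliers(st.n)
        rates = reaction_terms(st, mods, desk_params)
        for name in FIELD_NAMES:
            assert np.all(rates[name] == 0.0)

    def test_invalid_state_rejected(self, conservation_box, desk_params):
        dom, st, _ = conservation_box
        st.cm[0, 0] = -1.0
        with pytest.raises(FloatingPointError):
            reaction_terms(st, oxygen_multipliers(st.n), desk_params)
        st.cm[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            reaction_terms(st, oxygen_multipliers(st.n), desk_params)

    def test_dense_matrix_suppresses_proliferation(self, conservation_box,
                                                   desk_params):
        dom, _, _ = conservation_box
        st = StateFields.zeros(dom)
        st.cm += 0.1
        st.n += 4.0
        sparse = reaction_terms(st, oxygen_multipliers(st.n), desk_params)
        st_dense = st.copy()
        st_dense.mf += 1.0
        dense = reaction_terms(st_dense, oxygen_multipliers(st_dense.n),
                               desk_params)
        assert dense["cm"].max() < sparse["cm"].max()

    def test_high_gf_drives_chondrogenic_differentiation(self,
                                                         conservation_box,
                                                         desk_params):
        dom, _, _ = conservation_box
        st = StateFields.zeros(dom)
        st.cm += 0.1
        st.n += 3.0            # chondrogenic optimum
        low = reaction_terms(st, oxygen_multipliers(st.n), desk_params)
        st_hi = st.copy()
        st_hi.gbc += 10.0      # 1 ug/ml
        hi = reaction_terms(st_hi, oxygen_multipliers(st_hi.n), desk_params)
        assert hi["cc"].max() > low["cc"].max()
        assert hi["cm"].min() < low["cm"].min()


class TestDriver:
    def _simulation(self, params):
        from callusim.domain import BoundarySpec
        from callusim.scenarios import standard_compromised
        dom, st, net = toy_fixture("conservation_box")
        rng = np.random.default_rng(0)
        return Simulation(dom, st, net, BoundarySpec(), params,
                          standard_compromised(5.0), rng)

    def test_zero_rates_reduce_to_pure_transport(self, desk_params):
        p = _zero_reaction_params(desk_params)
        sim = self._simulation(p)
        ref = sim.state.copy()
        sim.step()
        transport_step(ref, sim.domain, None, p.solver.dt, p)
        # no vessels, zero rate constants: oxygen loses nothing either
        for name in ("cm", "cf", "gbc", "gv"):
            assert np.allclose(sim.state[name], ref[name], atol=1e-12)

    def test_events_report_death_zone(self, desk_params):
        sim = self._simulation(desk_params)
        ev = sim.step()
        assert 0.0 <= ev.death_zone_fraction <= 1.0
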