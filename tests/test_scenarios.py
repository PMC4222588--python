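import numpy as np
import pytest

import callusim as cs
from callusim.domain import build_domain, initial_state
from callusim.scenarios import (ScenarioSpec, Treatment, standard_compromised,
                                host_case, with_treatment, apply_treatment,
                                oat_design, toy_fixture,
                                oxygen_gradient_scenario)


class TestScenarioSpec:
    def test_standard_compromised_is_tenfold_reduced(self):
        sc = standard_compromised(5.0)
        assert sc.central["cm"] == pytest.approx(2e3)
        assert sc.central["gbc"] == pytest.approx(10.0)
        assert sc.central["cm"] / sc.peripheral["cm"] == pytest.approx(0.1)
        assert sc.central["gbc"] / sc.peripheral["gbc"] == pytest.approx(0.1)

    def test_yaml_round_trip_identity(self):
        sc = with_treatment(host_case("J", 4.0), 35.0, "combo",
                            cm=1e6, gbc=1e3)
        again = ScenarioSpec.from_yaml(sc.to_yaml())
        assert again.to_dict() == sc.to_dict()

    @pytest.mark.parametrize("letter", list("ABCDEFGHIJ"))
    def test_every_host_case_constructs(self, letter):
        sc = host_case(letter, 5.0)
        assert letter in sc.case_letters() or sc.case_letters()

    def test_invalid_case_rejected(self):
        with pytest.raises(ValueError):
            host_case("Q", 5.0)
        with pytest.raises(ValueError):
            ScenarioSpec(host_case="zz")

    def test_oxygen_gradient_scenario_matches_profile(self):
        sc = oxygen_gradient_scenario(5.0)
        dom = build_domain(5.0, 0.25)
        st = initial_state(dom, sc)
        central = dom.central_mask & dom.callus_mask
        X = np.broadcast_to(dom.x_centers, dom.shape)
        # n(x) = 0.8 %/mm * x, clipped to [0, 4] %
        expected = np.clip(0.8 * X, 0.0, 4.0)
        assert np.allclose(st.n[central], expected[central])


class TestTreatments:
    def test_zero_dose_is_a_no_op(self, domain_5mm):
        sc = standard_compromised(5.0)
        st = initial_state(domain_5mm, sc)
        before = st.copy()
        apply_treatment(st, domain_5mm, Treatment(0.0, "cells", cm=0.0), 0.0)
        for name, arr in st.items():
            assert np.array_equal(arr, before[name])

    def test_injection_cannot_remove_material(self, domain_5mm):
        sc = standard_compromised(5.0)
        st = initial_state(domain_5mm, sc)
        st.cm += 0.5
        apply_treatment(st, domain_5mm, Treatment(0.0, "cells", cm=2e5), 0.0)
        assert st.cm.min() >= 0.5          # replace-if-higher semantics

    def test_non_targeted_fields_conserved_exactly(self, domain_5mm):
        sc = standard_compromised(5.0)
        st = initial_state(domain_5mm, sc)
        before = st.copy()
        apply_treatment(st, domain_5mm,
                        Treatment(0.0, "combo", cm=1e6, gbc=1e3), 0.0)
        for name in ("cf", "cc", "cb", "mf", "mc", "mb", "gv", "n"):
            assert np.array_equal(st[name], before[name])
        central = domain_5mm.central_mask & domain_5mm.callus_mask
        assert st.cm[central].min() == pytest.approx(1.0)
        assert st.gbc[central].min() == pytest.approx(10.0)

    def test_scheduling_in_the_past_rejected(self, domain_5mm):
        st = initial_state(domain_5mm, standard_compromised(5.0))
        with pytest.raises(ValueError):
            apply_treatment(st, domain_5mm, Treatment(10.0, "gf", gbc=1e3),
                            t=20.0)

    def test_invalid_treatment_rejected(self):
        with pytest.raises(ValueError):
            Treatment(5.0, "pixie_dust")
        with pytest.raises(ValueError):
            Treatment(120.0, "cells", cm=1e5)
        with pytest.raises(ValueError):
            Treatment(5.0, "cells", cm=-1.0)


class TestOATDesign:
    def test_sweep_differs_in_exactly_one_parameter(self):
        base = standard_compromised(5.0)
        for sc in oat_design(base, "n_init", (0.5, 0.7, 3.7, 4.0)):
            diff = {k for k in base.central
                    if sc.central[k] != base.central[k]}
            assert diff <= {"n"}
            assert sc.gap_size == base.gap_size

    def test_gap_sweep_changes_only_gap(self):
        base = standard_compromised(5.0)
        designs = oat_design(base, "gap_size", (0.5, 1, 2, 3, 4, 5))
        assert [d.gap_size for d in designs] == [0.5, 1, 2, 3, 4, 5]
        assert all(d.central == base.central for d in designs)

    def test_empty_values_empty_design(self):
        assert oat_design(standard_compromised(5.0), "n_init", ()) == []

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            oat_design(standard_compromised(5.0), "gravity", (9.81,))


class TestToyFixtures:
    def test_conservation_box_is_all_callus(self, conservation_box):
        dom, st, net = conservation_box
        assert dom.callus_mask.all()
        assert net.n_ecs() == 0

    def test_gradient_corridor_has_linear_gv(self, gradient_corridor):
        dom, st, _ = gradient_corridor
        row = st.gv[0]
        diffs = np.diff(row)
        assert (diffs > 0).all()
        assert np.allclose(diffs, diffs[0])

    def test_notch_chain_fixture_alternates(self):
        from callusim.notch import resolve_fates
        from callusim.vasculature import _values_at
        dom, st, net = toy_fixture("notch_chain_6")
        pts = np.asarray(net.branches[0].points)
        gv = _values_at(st.gv, dom, pts)
        fates = resolve_fates(gv, rng=np.random.default_rng(0))
        tips = [i for i, f in enumerate(fates) if f == "tip"]
        assert len(tips) >= 2
        assert all(b - a >= 2 for a, b in zip(tips, tips[1:]))

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError):
            toy_fixture("tesseract")
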