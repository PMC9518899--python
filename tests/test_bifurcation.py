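"""Branch scans, fold/pitchfork location, and two-parameter structure."""

import numpy as np
import pytest

import growthfeedback as g
from growthfeedback import GrowthFeedbackParams
from growthfeedback.core_models import SelfActivationCircuit

SWEEP = (0.02, 2.0)


@pytest.fixture(scope="module")
def sa_diagram(self_activation):
    return g.branch_scan(self_activation, "kg0", SWEEP, n_grid=61)


@pytest.fixture(scope="module")
def toggle_diagram(toggle):
    return g.branch_scan(toggle, "kg0", SWEEP, n_grid=61)


class TestSelfActivationSweep:
    def test_four_saddle_nodes(self, sa_diagram):
        assert len(sa_diagram.saddle_nodes) == 4
        assert not sa_diagram.pitchforks
        labels = [e.label for e in sa_diagram.events]
        assert labels == ["SN1", "SN2", "SN3", "SN4"]

    def test_tristable_between_middle_saddle_nodes(self, sa_diagram):
        regions = g.classify_regions(sa_diagram)
        assert [r.label for r in regions] == ["mono", "bi", "tri", "bi", "mono"]

    def test_fold_crossing_changes_count_by_two(self, sa_diagram, self_activation):
        for ev in sa_diagram.saddle_nodes:
            eps = 1e-4
            n_lo = len(
                g.find_steady_states(self_activation.replace(kg0=ev.param_value - eps))
            )
            n_hi = len(
                g.find_steady_states(self_activation.replace(kg0=ev.param_value + eps))
            )
            assert abs(n_lo - n_hi) == 2


class TestToggleSweep:
    def test_two_saddle_nodes_one_pitchfork(self, toggle_diagram):
        assert len(toggle_diagram.saddle_nodes) == 2
        assert len(toggle_diagram.pitchforks) == 1

    def test_pitchfork_on_diagonal_with_stable_symmetric_mode(
        self, toggle_diagram, toggle
    ):
        pf = toggle_diagram.pitchforks[0]
        assert pf.state[0] == pytest.approx(pf.state[1], rel=1e-6)
        jac = toggle.replace(kg0=pf.param_value).jacobian(pf.state)
        anti = jac[0, 0] - jac[0, 1]
        sym = jac[0, 0] + jac[0, 1]
        assert abs(anti) < 1e-6  # the symmetry-breaking mode is critical
        assert sym < 0  # the symmetric direction stays attracting

    def test_tristability_between_first_fold_and_pitchfork(self, toggle_diagram):
        labels = [r.label for r in g.classify_regions(toggle_diagram)]
        assert labels == ["bi", "tri", "bi", "mono"]
        order = [e.type for e in toggle_diagram.events]
        assert order == ["saddle_node", "pitchfork", "saddle_node"]


class TestAsymmetricToggle:
    def test_one_percent_asymmetry_unfolds_pitchfork(self, toggle):
        asym = toggle.replace(k1_1=0.202)
        diag = g.branch_scan(asym, "kg0", SWEEP, n_grid=61)
        assert not diag.pitchforks
        assert len(diag.saddle_nodes) == 3
        assert any(r.n_stable == 3 for r in g.classify_regions(diag))

    def test_five_percent_asymmetry_same_structure(self, toggle):
        diag = g.branch_scan(toggle.replace(k1_1=0.21), "kg0", SWEEP, n_grid=61)
        assert not diag.pitchforks
        assert len(diag.saddle_nodes) == 3

    def test_pitchfork_locator_requires_symmetry(self, toggle):
        with pytest.raises(ValueError, match="symmetric"):
            g.locate_pitchfork(toggle.replace(k1_1=0.202), (0.9, 1.1))


class TestLocateFold:
    def test_constitutive_folds_bracket_reference_kg0(self, constitutive):
        diag = g.branch_scan(constitutive, "kg0", SWEEP, n_grid=41)
        sn = sorted(e.param_value for e in diag.saddle_nodes)
        assert len(sn) == 2
        assert sn[0] < 0.9 < sn[1]  # bistable at the reference kg0 = 0.9

    def test_zero_derivative_at_fold(self, constitutive):
        diag = g.branch_scan(constitutive, "kg0", SWEEP, n_grid=41)
        for ev in diag.saddle_nodes:
            at_fold = constitutive.replace(kg0=ev.param_value)
            assert abs(at_fold.jacobian(ev.state)[0, 0]) < 1e-8

    def test_k0_folds_match_analytic_window(self, constitutive):
        lo, hi = g.bistable_k0_range(constitutive)
        diag = g.branch_scan(constitutive, "k0", (0.01, 0.6), n_grid=41)
        folds = sorted(e.param_value for e in diag.saddle_nodes)
        assert folds[0] == pytest.approx(lo, rel=1e-8)
        assert folds[1] == pytest.approx(hi, rel=1e-8)

    def test_no_folds_without_ultrasensitivity(self, constitutive):
        diag = g.branch_scan(constitutive.replace(m=1.0), "kg0", SWEEP, n_grid=41)
        assert not diag.events

    def test_rejects_unknown_parameter(self, constitutive):
        with pytest.raises(ValueError):
            g.branch_scan(constitutive, "k9", SWEEP, n_grid=5)


class TestStructuralReductions:
    def test_degenerate_self_activation_matches_constitutive(self, constitutive):
        """With k1 = 0 the self-activation model is constitutive; the fold
        structure must coincide."""
        sa0 = SelfActivationCircuit(
            k0=0.1, k1=0.0, K=0.1, n=2, d0=0.0015,
            gf=GrowthFeedbackParams(0.9, 1.0, 2.0),
        )
        f_sa = sorted(
            e.param_value
            for e in g.branch_scan(sa0, "kg0", SWEEP, n_grid=41).saddle_nodes
        )
        f_c = sorted(
            e.param_value
            for e in g.branch_scan(constitutive, "kg0", SWEEP, n_grid=41).saddle_nodes
        )
        assert np.allclose(f_sa, f_c, rtol=1e-8)

    def test_fold_kg0_values_independent_of_J(self, constitutive):
        """Doubling J with k0 rescaled leaves the fold kg0 values unchanged."""
        rescaled = constitutive.replace(J=2.0, k0=0.2)
        f_a = sorted(
            e.param_value
            for e in g.branch_scan(constitutive, "kg0", SWEEP, n_grid=41).saddle_nodes
        )
        f_b = sorted(
            e.param_value
            for e in g.branch_scan(rescaled, "kg0", SWEEP, n_grid=41).saddle_nodes
        )
        assert np.allclose(f_a, f_b, rtol=1e-8)

    def test_region_classes_match_direct_enumeration(self, sa_diagram, self_activation):
        for r in g.classify_regions(sa_diagram):
            mid = 0.5 * (r.param_lo + r.param_hi)
            states = g.find_steady_states(self_activation.replace(kg0=mid))
            assert sum(s.stability == "stable" for s in states) == r.n_stable


class TestTwoParameterBoundary:
    def test_constitutive_fold_curves_merge_toward_m_one(self, constitutive):
        tb = g.two_parameter_boundary(
            constitutive, "m", "kg0", p1_values=[1.5, 1.75, 2.0],
            p2_range=SWEEP, n_grid=41,
        )
        gaps = {}
        for m, events in tb.events_by_p1.items():
            sn = sorted(e.param_value for e in events)
            assert len(sn) == 2
            gaps[m] = sn[1] - sn[0]
        assert gaps[1.5] < gaps[1.75] < gaps[2.0]
        assert "SN1" in tb.curves and "SN2" in tb.curves
        assert all(len(v) == 3 for v in tb.curves.values())

    def test_smallest_nonmonotonic_m_solves_quadratic(self, constitutive):
        """At kg0 = 0.9, d0 = 0.0015 the ratio is 600; the smallest m with a
        nonmonotonic loss curve solves 600 (m-1)^2 = 4 m (larger root)."""
        ratio = 0.9 / 0.0015
        m_crit = np.roots([ratio, -2 * ratio - 4, ratio]).max()
        assert m_crit == pytest.approx(1.0854, abs=1e-3)
        just_above = g.loss_curve_extrema(constitutive.replace(m=m_crit * 1.01))
        just_below = g.loss_curve_extrema(constitutive.replace(m=m_crit * 0.99))
        assert just_above.exists and not just_below.exists
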