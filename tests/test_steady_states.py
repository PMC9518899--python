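"""Global fixed-point enumeration, stability, nullclines and flow fields."""

import numpy as np
import pytest

import growthfeedback as g
from growthfeedback import GrowthFeedbackParams
from growthfeedback.core_models import ConstitutiveCircuit, SelfActivationCircuit
from growthfeedback.steady_states import search_upper_bound, steady_states_table


class TestReferenceFixtures:
    def test_constitutive_bistable(self, constitutive):
        states = g.find_steady_states(constitutive)
        assert [s.stability for s in states] == ["stable", "unstable", "stable"]

    def test_self_activation_tristable(self, self_activation):
        states = g.find_steady_states(self_activation)
        assert len(states) == 5
        assert sum(s.stability == "stable" for s in states) == 3
        # OFF / ON / super-ON ordering: growth rate drops across stable states
        stable = [s for s in states if s.stability == "stable"]
        grs = [s.growth_rate for s in stable]
        assert grs[0] > grs[1] > grs[2]

    def test_toggle_tristable(self, toggle):
        states = g.find_steady_states(toggle)
        assert len(states) == 5
        stable = [s for s in states if s.stability == "stable"]
        assert len(stable) == 3
        # stable set is {(lo, lo), (lo, hi), (hi, lo)}
        sums = sorted(float(s.state.sum()) for s in stable)
        assert sums[0] < 1.0 and sums[1] == pytest.approx(sums[2], rel=1e-6)
        asym = [s for s in stable if abs(s.state[0] - s.state[1]) > 1.0]
        assert len(asym) == 2

    def test_toggle_quadstable(self, toggle_quad):
        states = g.find_steady_states(toggle_quad)
        assert len(states) == 7
        stable = [s for s in states if s.stability == "stable"]
        assert len(stable) == 4
        # one stable state has both genes moderately co-expressed
        sym_stable = [s for s in stable if np.isclose(s.state[0], s.state[1])]
        mids = [s for s in sym_stable if 1.0 < s.state[0] < 5.0]
        assert len(mids) == 1

    def test_constant_growth_reduces_to_linear(self, constitutive):
        flat = constitutive.replace(J=1e9)
        states = g.find_steady_states(flat)
        assert len(states) == 1
        assert states[0].x == pytest.approx(0.1 / (0.0015 + 0.9), rel=1e-9)
        assert states[0].stability == "stable"


class TestOneDimensionalStructure:
    def test_alternation_and_stable_endpoints(self, rng):
        """1D steady states alternate stable/unstable with stable ends."""
        checked = 0
        for _ in range(60):
            model = ConstitutiveCircuit(
                k0=10 ** rng.uniform(-2, 0),
                d0=10 ** rng.uniform(-3, -1),
                gf=GrowthFeedbackParams(
                    kg0=rng.uniform(0.1, 2.0), J=10 ** rng.uniform(-0.5, 0.5),
                    m=rng.uniform(1.2, 3.0),
                ),
            )
            states = g.find_steady_states(model)
            labels = [s.stability for s in states]
            if "marginal" in labels:
                continue  # skip near-tangent draws
            assert len(states) % 2 == 1
            assert labels[0] == labels[-1] == "stable"
            assert all(
                a != b for a, b in zip(labels[:-1], labels[1:])
            ), "stability must alternate"
            checked += 1
        assert checked > 40

    def test_count_matches_dense_sign_scan(self, rng):
        """Root completeness against a brute-force sign-change oracle."""
        for _ in range(40):
            model = SelfActivationCircuit(
                k0=10 ** rng.uniform(-3, -1.5),
                k1=10 ** rng.uniform(-1, 0),
                K=10 ** rng.uniform(-1.5, 0),
                n=rng.uniform(1.0, 4.0),
                d0=10 ** rng.uniform(-2, -1),
                gf=GrowthFeedbackParams(
                    kg0=rng.uniform(0.2, 2.0), J=1.0, m=rng.uniform(1.0, 3.0)
                ),
            )
            states = g.find_steady_states(model)
            ub = search_upper_bound(model)
            grid = np.unique(
                np.concatenate(
                    [np.linspace(ub / 3e5, ub, 300_000), np.geomspace(ub * 1e-9, ub, 50_000)]
                )
            )
            vals = model.rhs(grid[:, None])[:, 0]
            oracle = int(np.sum(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0))
            assert len(states) == oracle

    def test_residuals_are_tiny(self, self_activation):
        scale = float(self_activation.max_production.max())
        for s in g.find_steady_states(self_activation):
            assert s.residual < 1e-9 * scale


class TestTwoDimensionalStructure:
    def test_count_invariant_under_seed_refinement(self, toggle, toggle_quad):
        for model in (toggle, toggle_quad):
            base = g.find_steady_states(model)
            fine = g.find_steady_states(model, seeds_per_axis=(32, 24))
            assert len(base) == len(fine)

    def test_swap_symmetry_of_state_set(self, toggle):
        states = g.find_steady_states(toggle)
        pts = np.array([s.state for s in states])
        for p in pts:
            assert np.min(np.max(np.abs(pts - p[::-1]), axis=1)) < 1e-6

    def test_saddle_spectrum(self, toggle_quad):
        saddles = [
            s
            for s in g.find_steady_states(toggle_quad)
            if s.stability == "unstable" and abs(s.state[0] - s.state[1]) > 0.1
        ]
        assert saddles
        for s in saddles:
            re = np.sort(s.eigenvalues.real)
            assert re[0] < 0 < re[-1]

    def test_growth_rate_consistency(self, toggle_quad):
        for s in g.find_steady_states(toggle_quad):
            assert s.growth_rate == pytest.approx(
                g.growth_rate(toggle_quad.gf, float(s.state.sum()))
            )


class TestClassifyAndValidate:
    def test_refuses_non_fixed_point(self, constitutive):
        with pytest.raises(ValueError, match="residual"):
            g.classify_stability(constitutive, [5.0])

    def test_zero_basal_production_rejected(self, constitutive):
        with pytest.raises(ValueError, match="basal production"):
            g.find_steady_states(constitutive.replace(k0=0.0))

    def test_export_table_columns(self, toggle):
        df = steady_states_table(g.find_steady_states(toggle))
        for col in ("x1", "x2", "stability", "eig_re_1", "eig_re_2",
                    "growth_rate", "residual"):
            assert col in df.columns
        assert len(df) == 5


class TestNullclines:
    def test_intersections_reproduce_fixed_points(self, toggle, toggle_quad):
        for model, expected in ((toggle, 5), (toggle_quad, 7)):
            ns = g.nullclines(model, resolution=500)
            pts = ns.intersections()
            assert len(pts) == expected
            states = np.array([s.state for s in g.find_steady_states(model)])
            for p in pts:
                assert np.min(np.max(np.abs(states - p), axis=1)) < 0.05

    def test_mirror_symmetry(self, toggle):
        ns = g.nullclines(toggle, resolution=400)
        pts = np.array(ns.intersections())
        for p in pts:
            assert np.min(np.max(np.abs(pts - p[::-1]), axis=1)) < 0.05

    def test_requires_two_genes(self, constitutive):
        with pytest.raises(ValueError):
            g.nullclines(constitutive)


class TestDirectionField:
    def test_one_dimensional_signs(self, constitutive):
        lo, thr, hi = g.find_steady_states(constitutive)
        field = g.direction_field(constitutive, (0.0, 1.2 * hi.x), grid=200)
        x = field.points[:, 0]
        v = field.vectors[:, 0]
        between = (x > 1.05 * thr.x) & (x < 0.95 * hi.x)
        assert np.all(v[between] > 0)
        below = (x > 1.05 * lo.x) & (x < 0.95 * thr.x)
        assert np.all(v[below] < 0)
        assert v[0] > 0  # flow away from the origin: basal production

    def test_vectors_point_into_stable_node(self, toggle):
        stable = [s for s in g.find_steady_states(toggle) if s.stability == "stable"]
        target = stable[0].state
        r = 0.05
        for angle in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            p = target + r * np.array([np.cos(angle), np.sin(angle)])
            if np.any(p < 0):
                continue
            radial = float(np.dot(toggle.rhs(p), p - target))
            assert radial < 0

    def test_zero_flag_at_fixed_point(self, constitutive):
        states = g.find_steady_states(constitutive)
        field = g.direction_field(
            constitutive, (states[0].x, states[0].x), grid=1
        )
        assert field.zero_mask[0]
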