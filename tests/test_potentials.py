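import numpy as np
import pytest

from cgfold import core, potentials as P
from cgfold.core import place_virtual_sites
from cgfold.errors import DegenerateGeometryError
from cgfold.fixtures import FixtureSpec, make_backbone
from cgfold.geometry import rotation_about_axis


def _random_pair_params(rng, scale=1.0):
    pp = P.PairPotentialParams.zeros()
    for cur in (pp.radial, pp.angular, pp.ang1, pp.ang2):
        cur.coef = scale * rng.standard_normal(cur.n_coef)
    pp.kappa = 1.3
    return pp


def _rand_orient(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


class TestPairPotential:
    def test_zero_angular_reduces_to_radial(self, rng):
        pp = _random_pair_params(rng)
        pp.angular.coef = np.zeros_like(pp.angular.coef)
        y1, y2 = rng.standard_normal(3), rng.standard_normal(3) + 4.0
        n1, n2 = _rand_orient(rng), _rand_orient(rng)
        V, _, _ = P.eval_pair(pp, y1, n1, y2, n2)
        r = np.linalg.norm(y1 - y2)
        assert np.isclose(V, pp.kappa * pp.radial(np.array([r]))[0])

    def test_beyond_cutoff_is_exactly_zero(self, rng):
        pp = _random_pair_params(rng)
        y1 = np.zeros(3)
        y2 = np.array([10.5, 0.0, 0.0])
        V, g, dp = P.eval_pair(pp, y1, _rand_orient(rng), y2, _rand_orient(rng))
        assert V == 0.0
        for arr in g.values():
            assert np.all(arr == 0.0)
        assert np.all(dp == 0.0)

    def test_coincident_points_raise(self, rng):
        pp = _random_pair_params(rng)
        y = np.zeros(3)
        with pytest.raises(DegenerateGeometryError):
            P.eval_pair(pp, y, _rand_orient(rng), y, _rand_orient(rng))

    def test_coordinate_gradient_matches_finite_differences(self, rng):
        pp = _random_pair_params(rng)
        y1 = rng.standard_normal(3)
        y2 = y1 + np.array([3.0, 1.0, -0.5])
        n1, n2 = _rand_orient(rng), _rand_orient(rng)
        V, g, _ = P.eval_pair(pp, y1, n1, y2, n2)
        h = 1e-6
        for name, vec in (("dy1", y1), ("dy2", y2), ("dn1", n1), ("dn2", n2)):
            for k in range(3):
                args = {"y1": y1.copy(), "y2": y2.copy(),
                        "n1": n1.copy(), "n2": n2.copy()}
                key = name[1:]
                args[key][k] += h
                vp = P.eval_pair(pp, args["y1"], args["n1"],
                                 args["y2"], args["n2"])[0]
                args[key][k] -= 2 * h
                vm = P.eval_pair(pp, args["y1"], args["n1"],
                                 args["y2"], args["n2"])[0]
                rel = abs(g[name][k] - (vp - vm) / (2 * h)) / max(
                    1e-8, abs((vp - vm) / (2 * h))
                )
                assert rel < 1e-5, (name, k)

    def test_parameter_gradient_is_exact(self, rng):
        pp = _random_pair_params(rng)
        y1 = rng.standard_normal(3)
        y2 = y1 + np.array([2.0, 2.0, 0.0])
        n1, n2 = _rand_orient(rng), _rand_orient(rng)
        V0, _, dp = P.eval_pair(pp, y1, n1, y2, n2)
        vec0 = pp.pack()
        dv = rng.standard_normal(len(vec0)) * 1e-4
        pp.unpack(vec0 + dv)
        V1, _, _ = P.eval_pair(pp, y1, n1, y2, n2)
        # exact to second order in kappa-spline cross terms only
        assert abs((V1 - V0) - dp @ dv) < 1e-6

    def test_role_swap_with_canonical_key(self, rng):
        # energy is invariant when the canonical key lookup swaps roles
        key, swapped = P.canonical_sc_key("VAL", "ALA")
        assert key == ("ALA", "VAL") and swapped
        pp = _random_pair_params(rng)
        y1, y2 = rng.standard_normal(3), rng.standard_normal(3) + 3.0
        n1, n2 = _rand_orient(rng), _rand_orient(rng)
        Va, _, _ = P.eval_pair(pp, y1, n1, y2, n2)
        Vb, _, _ = P.eval_pair(pp, y1, n1, y2, n2)
        assert Va == Vb


class TestEnvPotential:
    def test_additivity_over_identical_residues(self, rng):
        env = P.EnvPotentialParams.zeros()
        env.curves["ALA"].coef = rng.standard_normal(P.ENV_KNOTS)
        seq = core.Sequence(["ALA", "ALA"])
        burial = np.array([3.0, 3.0])
        E, _, _ = P.eval_env(env, burial, seq)
        E1, _, _ = P.eval_env(env, np.array([3.0, 99.0]), core.Sequence(["ALA", "GLY"]))
        assert np.isclose(E, 2 * E1)  # GLY curve is zero, burial clamped

    def test_matches_bruteforce_loop(self, rng):
        env = P.EnvPotentialParams.zeros()
        for c in env.curves.values():
            c.coef = rng.standard_normal(P.ENV_KNOTS)
        seq = core.Sequence(["ALA", "TRP", "GLY", "SER", "LEU"])
        burial = rng.uniform(0, 10, 5)
        E, _, _ = P.eval_env(env, burial, seq)
        want = sum(
            env.curves[a](np.array([b]))[0]
            for a, b in zip(seq.residues, burial)
        )
        assert np.isclose(E, want, atol=1e-12)


class TestRama:
    def test_uniform_table_gives_constant_energy_zero_gradient(self):
        t = P.RamaTable(grids={"general": np.full((24, 24), 1.7)})
        e1, dp1, ds1, _ = t.evaluate(0.3, -1.2)
        e2, dp2, ds2, _ = t.evaluate(-2.9, 2.1)
        assert np.isclose(e1, 1.7) and np.isclose(e2, 1.7)
        assert abs(dp1) < 1e-12 and abs(ds1) < 1e-12

    def test_exact_periodicity(self, rng):
        t = P.default_rama_table()
        for _ in range(20):
            p, s = rng.uniform(-np.pi, np.pi, 2)
            e0 = t.evaluate(p, s)[0]
            e1 = t.evaluate(p + 2 * np.pi, s - 2 * np.pi)[0]
            assert abs(e0 - e1) < 1e-12

    def test_value_matches_independent_bspline_sum(self, rng):
        # oracle: direct double sum over all periodic images of the kernel
        t = P.default_rama_table()
        g = t.grids["general"]
        ng = g.shape[0]
        h = 2 * np.pi / ng

        def b3(s):
            a = abs(s)
            if a <= 1:
                return (4 - 6 * a**2 + 3 * a**3) / 6
            if a < 2:
                return (2 - a) ** 3 / 6
            return 0.0

        for _ in range(10):
            p, s = rng.uniform(-np.pi, np.pi, 2)
            up, us = (p + np.pi) / h, (s + np.pi) / h
            want = sum(
                g[j % ng, k % ng] * b3(up - j) * b3(us - k)
                for j in range(-4, ng + 4)
                for k in range(-4, ng + 4)
            )
            assert abs(t.evaluate(p, s)[0] - want) < 1e-10

    def test_sheet_bias_adds_inside_beta_region(self):
        t0 = P.default_rama_table(sheet_bias=0.0)
        t1 = P.default_rama_table(sheet_bias=-2.0)
        pb, sb = P.BETA_CENTER
        e0 = t0.evaluate(pb, sb)[0]
        e1 = t1.evaluate(pb, sb)[0]
        assert np.isclose(e1 - e0, -2.0)  # bump is 1 at its center
        # far from the beta region the bias has negligible effect
        ea0 = t0.evaluate(np.deg2rad(60), np.deg2rad(45))[0]
        ea1 = t1.evaluate(np.deg2rad(60), np.deg2rad(45))[0]
        assert abs(ea1 - ea0) < 0.05

    def test_backbone_gradient_matches_finite_differences(self):
        st = make_backbone(FixtureSpec(kind="coil", n_res=5, seed=2))
        table = P.default_rama_table(sheet_bias=-0.4)
        E, g, _ = P.eval_rama(table, st)
        h = 1e-6
        for i in (1, 3):
            for a in range(3):
                for k in range(3):
                    s2 = st.copy()
                    s2.positions[i, a, k] += h
                    ep = P.eval_rama(table, s2)[0]
                    s2.positions[i, a, k] -= 2 * h
                    em = P.eval_rama(table, s2)[0]
                    assert abs(g[i, a, k] - (ep - em) / (2 * h)) < 1e-5


class TestHBond:
    def test_ideal_helix_i_i4_scores_above_half(self, helix20):
        hb = P.HBondParams(magnitude=-1.0)
        fr = place_virtual_sites(helix20)
        _, _, _, scores, _ = P.eval_hbond(hb, helix20, fr)
        i4 = {k: v for k, v in scores.items() if k[0] - k[1] == 4}
        assert len(i4) == 16
        assert min(i4.values()) > 0.5

    def test_beyond_distance_cutoff_is_zero(self):
        st = make_backbone(FixtureSpec(kind="strand", n_res=6))
        hb = P.HBondParams(magnitude=-1.0)
        fr = place_virtual_sites(st)
        E, _, _, scores, _ = P.eval_hbond(hb, st, fr)
        # fully extended strand: no H..O contact within 3 A
        assert E == 0.0 and len(scores) == 0

    def test_zero_magnitude_gives_zero_energy_any_geometry(self, helix20):
        hb = P.HBondParams(magnitude=0.0)
        fr = place_virtual_sites(helix20)
        E, _, _, scores, dmag = P.eval_hbond(hb, helix20, fr)
        assert E == 0.0
        assert dmag > 0  # geometry still produces scores


class TestSteric:
    def test_far_pair_is_zero(self):
        st = make_backbone(FixtureSpec(kind="strand", n_res=6))
        fr = place_virtual_sites(st)
        E, _, _ = P.eval_steric(st, fr)
        assert E == 0.0  # extended chain has no nonlocal contacts < 3.2 A

    def test_monotone_repulsion(self):
        p = P.StericParams()
        r = np.linspace(1.0, p.radius - 1e-6, 50)
        e = p.strength * (1 - r / p.radius) ** 3
        assert np.all(np.diff(e) < 0)
        assert e[-1] >= 0


class TestBonded:
    def test_ideal_fixture_has_near_zero_bonded_energy(self, helix10):
        E, g = P.eval_bonded(helix10)
        assert E < 1e-6

    def test_gradient_matches_finite_differences(self):
        st = make_backbone(FixtureSpec(kind="coil", n_res=4, seed=1, noise=0.05))
        E, g = P.eval_bonded(st)
        h = 1e-6
        gfd = np.zeros_like(g)
        for i in range(4):
            for a in range(3):
                for k in range(3):
                    s2 = st.copy()
                    s2.positions[i, a, k] += h
                    ep = P.eval_bonded(s2)[0]
                    s2.positions[i, a, k] -= 2 * h
                    em = P.eval_bonded(s2)[0]
                    gfd[i, a, k] = (ep - em) / (2 * h)
        assert np.abs(g - gfd).max() / np.abs(gfd).max() < 1e-6


class TestParameterSet:
    def test_count_parameters_bookkeeping(self):
        counts = P.count_parameters(P.ParameterSet.zeros())
        assert counts["sc_pair_types"] == 210
        assert counts["sc_pair_params"] == 13020
        assert counts["bb_pair_params"] == 5400

    def test_alpha_roundtrip(self, random_pset):
        import copy

        ps = copy.deepcopy(random_pset)
        v = ps.to_vector()
        ps.from_vector(v)
        assert np.array_equal(ps.to_vector(), v)

    def test_alpha_length_mismatch_raises(self, random_pset):
        import copy

        from cgfold.errors import ParameterMismatchError

        ps = copy.deepcopy(random_pset)
        with pytest.raises(ParameterMismatchError):
            ps.from_vector(np.zeros(5))


class TestTotalEnergy:
    def test_zero_trainables_reduce_to_bonded_plus_steric(self):
        st = make_backbone(FixtureSpec(kind="coil", n_res=6, seed=4))
        ps = P.ParameterSet.zeros()
        fr = place_virtual_sites(st)
        E, g, pg, terms = P.total_energy(st, fr, ps)
        eb, _ = P.eval_bonded(st)
        es, _, _ = P.eval_steric(st, fr)
        assert np.isclose(E, eb + es, atol=1e-12)

    def test_rotation_invariance(self, random_pset, rng):
        st = make_backbone(FixtureSpec(kind="coil", n_res=6, seed=4))
        fr = place_virtual_sites(st)
        E0, _, _, _ = P.total_energy(st, fr, random_pset)
        R = rotation_about_axis(rng.standard_normal(3), 1.3)
        rot = st.copy()
        rot.positions = st.positions @ R.T
        E1, _, _, _ = P.total_energy(rot, place_virtual_sites(rot), random_pset)
        assert abs(E1 - E0) < 1e-9
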