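import itertools

import numpy as np
import pytest

from cgfold import core
from cgfold.core import place_virtual_sites
from cgfold.fixtures import FixtureSpec, make_backbone
from cgfold.potentials import ParameterSet
from cgfold.sidechain import (
    RotamerGraph,
    RotamerLibrary,
    build_rotamer_graph,
    fixture_library,
    run_bp,
    sidechain_forces,
)


def synthetic_graph(rng, edge_spec, n_nodes, max_states=6):
    """Random node/edge energies on a given topology (no geometry)."""
    ns = [int(rng.integers(1, max_states + 1)) for _ in range(n_nodes)]
    return RotamerGraph(
        state=None, frame=None, pset=None,
        pos=[np.zeros((s, 3)) for s in ns],
        orient=[np.zeros((s, 3)) for s in ns],
        local_pos=None, local_orient=None,
        log_prior=[np.log(rng.dirichlet(np.ones(s))) for s in ns],
        node_energy=[rng.standard_normal(s) * 2 for s in ns],
        edges=[
            (i, j, rng.standard_normal((ns[i], ns[j])) * scale)
            for (i, j, scale) in edge_spec
        ],
    )


def enumerate_reference(graph, T):
    """Exact -T log Z and marginals by exhaustive enumeration."""
    ns = [graph.n_states(i) for i in range(graph.n_nodes)]
    logw = []
    states = list(itertools.product(*[range(s) for s in ns]))
    for st in states:
        lw = sum(
            graph.log_prior[i][st[i]] - graph.node_energy[i][st[i]] / T
            for i in range(graph.n_nodes)
        )
        lw -= sum(tab[st[i], st[j]] / T for (i, j, tab) in graph.edges)
        logw.append(lw)
    logw = np.array(logw)
    m = logw.max()
    lz = m + np.log(np.exp(logw - m).sum())
    p = np.exp(logw - lz)
    marg = [np.zeros(s) for s in ns]
    for pi, st in zip(p, states):
        for i in range(graph.n_nodes):
            marg[i][st[i]] += pi
    return -T * lz, marg


class TestRunBP:
    def test_single_node_closed_form(self, rng):
        g = synthetic_graph(rng, [], 1, max_states=6)
        T = 1.3
        b = run_bp(g, T)
        w = np.exp(g.log_prior[0])
        boltz = w * np.exp(-g.node_energy[0] / T)
        Z = boltz.sum()
        assert np.allclose(b.node_marginals[0], boltz / Z, atol=1e-12)
        assert abs(b.free_energy - (-T * np.log(Z))) < 1e-12

    def test_trees_match_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            edges = [(int(rng.integers(0, i)), i, 1.5) for i in range(1, n)]
            g = synthetic_graph(rng, edges, n)
            T = float(rng.uniform(0.5, 2.0))
            b = run_bp(g, T, tol=1e-13, max_iter=300)
            F, marg = enumerate_reference(g, T)
            assert abs(b.free_energy - F) < 1e-10
            for i in range(n):
                assert np.abs(b.node_marginals[i] - marg[i]).max() < 1e-10

    def test_weak_4cycle_close_to_enumeration(self):
        rng = np.random.default_rng(7)
        edges = [(0, 1, 0.1), (1, 2, 0.1), (2, 3, 0.1), (0, 3, 0.1)]
        g = synthetic_graph(rng, edges, 4)
        b = run_bp(g, 1.0, tol=1e-12, max_iter=300)
        F, marg = enumerate_reference(g, 1.0)
        assert abs(b.free_energy - F) < 1e-3
        for i in range(4):
            assert np.abs(b.node_marginals[i] - marg[i]).sum() / 2 < 1e-3

    def test_edge_marginal_consistency(self, rng):
        edges = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0), (2, 3, 1.0)]
        g = synthetic_graph(rng, edges, 4)
        b = run_bp(g, 1.0, tol=1e-12, max_iter=500)
        assert b.converged
        for k, (i, j, _) in enumerate(g.edges):
            bm = b.edge_marginals[k]
            assert np.abs(bm.sum(axis=1) - b.node_marginals[i]).max() < 1e-8
            assert np.abs(bm.sum(axis=0) - b.node_marginals[j]).max() < 1e-8
            assert abs(bm.sum() - 1.0) < 1e-10

    def test_zero_temperature_limit_reaches_ground_state(self, rng):
        for _ in range(5):
            n = 4
            edges = [(int(rng.integers(0, i)), i, 1.0) for i in range(1, n)]
            g = synthetic_graph(rng, edges, n)
            b = run_bp(g, 0.01, tol=1e-13, max_iter=500)
            # ground state by enumeration (ignore priors at T->0)
            ns = [g.n_states(i) for i in range(n)]
            best = np.inf
            for st in itertools.product(*[range(s) for s in ns]):
                e = sum(g.node_energy[i][st[i]] for i in range(n))
                e += sum(tab[st[i], st[j]] for (i, j, tab) in g.edges)
                best = min(best, e)
            assert abs(b.free_energy - best) < 0.15  # residual T*entropy

    def test_free_energy_bounds(self, rng):
        n = 4
        edges = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)]
        g = synthetic_graph(rng, edges, n)
        # uniform priors: the entropy bound below assumes them
        g.log_prior = [
            np.full(g.n_states(i), -np.log(g.n_states(i))) for i in range(n)
        ]
        T = 1.0
        b = run_bp(g, T, tol=1e-13, max_iter=300)
        F, _ = enumerate_reference(g, T)
        ns = [g.n_states(i) for i in range(n)]
        emin = min(
            sum(g.node_energy[i][st[i]] for i in range(n))
            + sum(tab[st[i], st[j]] for (i, j, tab) in g.edges)
            for st in itertools.product(*[range(s) for s in ns])
        )
        assert b.free_energy <= emin + T * sum(np.log(s) for s in ns) + 1e-9
        assert b.free_energy >= F - 1e-9  # exact on trees; equality here

    def test_rejects_nonpositive_temperature(self, rng):
        g = synthetic_graph(rng, [], 1)
        with pytest.raises(ValueError):
            run_bp(g, 0.0)


class TestGraphConstruction:
    def test_distant_residues_have_no_edge(self):
        st = make_backbone(FixtureSpec(kind="strand", n_res=2, sequence="MK"))
        st.positions[1] += 50.0
        fr = place_virtual_sites(st)
        g = build_rotamer_graph(st, fr, ParameterSet.zeros(), fixture_library())
        assert g.n_nodes == 2 and len(g.edges) == 0

    def test_edge_list_matches_bruteforce_distance_scan(self, random_pset):
        st = make_backbone(
            FixtureSpec(kind="coil", n_res=7, sequence="MKWLFRE", seed=11)
        )
        fr = place_virtual_sites(st)
        lib = fixture_library()
        g = build_rotamer_graph(st, fr, random_pset, lib)
        cutoff = next(iter(random_pset.sc_pairs.values())).cutoff
        want = []
        for i in range(7):
            for j in range(i + 1, 7):
                dmin = np.min(np.linalg.norm(
                    np.asarray(g.pos[i])[:, None, :]
                    - np.asarray(g.pos[j])[None, :, :], axis=2,
                ))
                if dmin < cutoff:
                    want.append((i, j))
        assert [(i, j) for i, j, _ in g.edges] == want

    def test_polyalanine_has_single_state_nodes(self, helix10, random_pset):
        fr = place_virtual_sites(helix10)
        g = build_rotamer_graph(helix10, fr, random_pset, fixture_library())
        assert all(g.n_states(i) == 1 for i in range(10))

    def test_pair_table_consistent_under_role_swap(self, random_pset):
        # (VAL, ALA) pair must use the canonical (ALA, VAL) parameters with
        # roles swapped; energy of the physical configuration is unchanged
        st = make_backbone(FixtureSpec(kind="strand", n_res=2, sequence="VA"))
        fr = place_virtual_sites(st)
        g = build_rotamer_graph(st, fr, random_pset, fixture_library())
        st2 = make_backbone(FixtureSpec(kind="strand", n_res=2, sequence="VA"))
        fr2 = place_virtual_sites(st2)
        g2 = build_rotamer_graph(st2, fr2, random_pset, fixture_library())
        assert np.allclose(g.edges[0][2], g2.edges[0][2])


class TestForces:
    def test_no_edges_flat_nodes_give_zero_pair_force(self, random_pset):
        st = make_backbone(FixtureSpec(kind="strand", n_res=2, sequence="MK"))
        st.positions[1] += 60.0  # far: no edges, no bead-backbone contacts
        fr = place_virtual_sites(st)
        g = build_rotamer_graph(st, fr, random_pset, fixture_library())
        assert len(g.edges) == 0
        b = run_bp(g, 1.0)
        res = sidechain_forces(g, b)
        assert np.allclose(res.backbone_grad, 0.0, atol=1e-12)

    def test_forces_sum_to_zero(self, random_pset):
        st = make_backbone(
            FixtureSpec(kind="coil", n_res=6, sequence="MKWLFR", seed=5)
        )
        fr = place_virtual_sites(st)
        g = build_rotamer_graph(st, fr, random_pset, fixture_library())
        b = run_bp(g, 1.0, tol=1e-12, max_iter=300)
        res = sidechain_forces(g, b)
        net = res.backbone_grad.reshape(-1, 3).sum(axis=0)
        assert np.abs(net).max() < 1e-8

    def test_gradient_matches_finite_difference_of_free_energy(
        self, random_pset
    ):
        # 3 bulky residues; dF/dx vs central differences of the converged
        # Bethe free energy (envelope theorem at the BP fixed point)
        st = make_backbone(
            FixtureSpec(kind="coil", n_res=3, sequence="MKW", seed=6)
        )

        def F_of(positions):
            s2 = st.copy()
            s2.positions = positions
            fr = place_virtual_sites(s2)
            g = build_rotamer_graph(s2, fr, random_pset, fixture_library())
            return run_bp(g, 1.0, tol=1e-13, max_iter=500).free_energy

        fr = place_virtual_sites(st)
        g = build_rotamer_graph(st, fr, random_pset, fixture_library())
        b = run_bp(g, 1.0, tol=1e-13, max_iter=500)
        res = sidechain_forces(g, b)
        h = 1e-5
        rng = np.random.default_rng(0)
        for _ in range(6):
            i = int(rng.integers(3))
            a = int(rng.integers(3))
            k = int(rng.integers(3))
            p = st.positions.copy()
            p[i, a, k] += h
            fp = F_of(p)
            p[i, a, k] -= 2 * h
            fm = F_of(p)
            fd = (fp - fm) / (2 * h)
            assert abs(res.backbone_grad[i, a, k] - fd) < 1e-5 * max(
                1.0, abs(fd)
            )


def test_library_roundtrip_and_validation():
    lib = fixture_library()
    d = lib.to_dict()
    lib2 = RotamerLibrary.from_dict(d)
    for aa in ("ALA", "LEU", "ARG"):
        assert lib2.n_states(aa) == lib.n_states(aa)
    with pytest.raises(Exception):
        RotamerLibrary.from_dict({"version": 99, "residues": {}})
    with pytest.raises(ValueError):
        RotamerLibrary({"ALA": []})
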