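import copy

import numpy as np
import pytest

from cgfold import core
from cgfold.analysis import ca_rmsd
from cgfold.errors import ParameterMismatchError
from cgfold.fixtures import FixtureSpec, make_backbone
from cgfold.model import EnergyModel
from cgfold.potentials import ParameterSet
from cgfold.training import (
    CDConfig,
    Ensemble,
    RestraintSpec,
    cd_delta,
    cd_update,
    cd_update_vector,
    make_minibatches,
    sample_free_ensemble,
    sample_restrained_ensemble,
    training_loop,
)


def _fast_config(**kw):
    defaults = dict(
        sim_time=0.4, dt=0.01, n_replicas=2, t_min=1.0, base_interval=0.2,
        save_interval=10, swap_period=30, equil_fraction=0.5, seed=0,
        minibatch_size=1, step_size=0.01,
    )
    defaults.update(kw)
    return CDConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_model():
    return EnergyModel(ParameterSet.demo())


@pytest.fixture(scope="module")
def helix8():
    return make_backbone(FixtureSpec(kind="helix", n_res=8))


class TestEnsembles:
    def test_equilibration_discard_arithmetic(self):
        # 40 MD steps, save every 10 -> 4 saved; discard half -> 2 retained
        cfg = _fast_config()
        st = make_backbone(FixtureSpec(kind="helix", n_res=8))
        model = EnergyModel(ParameterSet.demo(), include_sidechain=False)
        ens = sample_free_ensemble(st, model, cfg)
        assert ens.n_frames == 2

    def test_dvda_matches_independent_reevaluation(self, tiny_model, helix8):
        cfg = _fast_config()
        ens = sample_free_ensemble(helix8, tiny_model, cfg)
        for f, dv in zip(ens.frames, ens.dvda):
            s = helix8.copy()
            s.positions = f
            res = tiny_model.evaluate(s, temperature=1.0)
            assert np.allclose(res.param_grad, dv, atol=1e-10)

    def test_fixed_seed_reproduces_ensemble_bitwise(self, tiny_model, helix8):
        cfg = _fast_config()
        a = sample_free_ensemble(
            helix8, tiny_model, cfg, rng=np.random.default_rng(5)
        )
        b = sample_free_ensemble(
            helix8, tiny_model, cfg, rng=np.random.default_rng(5)
        )
        assert all(np.array_equal(x, y) for x, y in zip(a.frames, b.frames))
        assert np.array_equal(a.dvda, b.dvda)


class TestRestraint:
    def test_zero_at_reference(self, helix8):
        r = RestraintSpec(reference=helix8.positions[:, core.CA].copy())
        e, f = r.energy_forces(helix8)
        assert e == 0.0 and np.all(f == 0.0)

    def test_zero_inside_flat_bottom(self, helix8, rng):
        r = RestraintSpec(
            reference=helix8.positions[:, core.CA].copy(), radius=1.0
        )
        s = helix8.copy()
        s.positions = s.positions + 0.05 * rng.standard_normal(s.positions.shape)
        e, f = r.energy_forces(s)
        assert e == 0.0

    def test_force_matches_finite_differences(self, helix8, rng):
        ref = helix8.positions[:, core.CA].copy()
        r = RestraintSpec(reference=ref, radius=0.1, spring=37.0)
        s = helix8.copy()
        s.positions = s.positions + 0.4 * rng.standard_normal(s.positions.shape)
        e, f = r.energy_forces(s)
        assert e > 0
        h = 1e-6
        for _ in range(5):
            i, k = int(rng.integers(8)), int(rng.integers(3))
            s2 = s.copy()
            s2.positions[i, core.CA, k] += h
            ep = r.energy_forces(s2)[0]
            s2.positions[i, core.CA, k] -= 2 * h
            em = r.energy_forces(s2)[0]
            assert abs(-f[i, core.CA, k] - (ep - em) / (2 * h)) < 1e-5

    def test_restrained_ensemble_stays_near_reference(self):
        """Mean best-fit Ca-RMSD of a restrained run stays within the
        flat-bottom radius plus thermal fluctuation."""
        st = make_backbone(FixtureSpec(kind="helix", n_res=10))
        model = EnergyModel(ParameterSet.demo())
        cfg = _fast_config(sim_time=1.0, save_interval=10)
        ens = sample_restrained_ensemble(
            st, model, cfg, rng=np.random.default_rng(3)
        )
        ref = st.positions[:, core.CA]
        rmsds = [
            ca_rmsd(f[:, core.CA], ref, exclude_termini=0)
            for f in ens.frames
        ]
        assert np.mean(rmsds) <= 1.5


class TestCDUpdate:
    def test_identical_ensembles_leave_alpha_unchanged(self):
        rng = np.random.default_rng(0)
        dv = rng.standard_normal((5, 7))
        e1 = Ensemble(frames=[None] * 5, energies=np.zeros(5), dvda=dv)
        e2 = Ensemble(frames=[None] * 5, energies=np.zeros(5), dvda=dv.copy())
        a = np.arange(7.0)
        a2 = cd_update_vector(a, [(e1, e2)], eps=0.3, m=1)
        assert np.array_equal(a, a2)

    def test_update_rule_exactness_on_frozen_ensembles(self):
        rng = np.random.default_rng(1)
        P = 11
        batch = []
        for _ in range(3):
            r = Ensemble([None] * 4, np.zeros(4), rng.standard_normal((4, P)))
            f = Ensemble([None] * 6, np.zeros(6), rng.standard_normal((6, P)))
            batch.append((r, f))
        eps, m = 0.17, 3
        a0 = rng.standard_normal(P)
        a1 = cd_update_vector(a0, batch, eps, m)
        want = a0 + (eps / m) * sum(
            f.dvda.mean(0) - r.dvda.mean(0) for r, f in batch
        )
        assert np.abs(a1 - want).max() < 1e-12

    def test_dimension_mismatch_raises(self):
        e = Ensemble([None], np.zeros(1), np.zeros((1, 4)))
        with pytest.raises(ParameterMismatchError):
            cd_delta([(e, e)], n_alpha=7)

    def test_update_sign_matches_maximum_likelihood_gradient(self):
        """1-D harmonic toy with exact sampling: the CD step moves k toward
        the generating k* from either side (the ML ascent direction)."""
        rng = np.random.default_rng(2)
        T, kstar = 1.0, 2.0

        def ens(k, n=4000):
            x = rng.normal(0.0, np.sqrt(T / (2 * k)), n)
            return Ensemble([None] * n, k * x**2, (x**2)[:, None])

        data = ens(kstar, 8000)
        for k0 in (0.5, 8.0):
            free = ens(k0, 8000)
            k1 = cd_update_vector(np.array([k0]), [(data, free)], 0.5, 1)
            assert np.sign(k1[0] - k0) == np.sign(kstar - k0)

    def test_parameter_recovery_within_ten_percent(self):
        """CD from a 4x mismatched start recovers the generating spring
        constant of the exactly-sampleable harmonic toy."""
        rng = np.random.default_rng(3)
        T, kstar = 1.0, 2.0

        def ens(k, n=2000):
            x = rng.normal(0.0, np.sqrt(T / (2 * k)), n)
            return Ensemble([None] * n, k * x**2, (x**2)[:, None])

        data = ens(kstar, 4000)
        k = np.array([0.5])
        for _ in range(200):
            k = cd_update_vector(k, [(data, ens(float(k[0])))], 0.5, 1)
            k = np.maximum(k, 0.05)
        assert abs(k[0] - kstar) / kstar < 0.10

    def test_nontrainable_constants_never_mutated(self, helix8, tiny_model):
        cfg = _fast_config()
        pset = ParameterSet.demo()
        before = copy.deepcopy(pset)
        bb = EnergyModel(pset, include_sidechain=False)
        ens_r = sample_restrained_ensemble(helix8, bb, cfg)
        ens_f = sample_free_ensemble(helix8, bb, cfg)
        new, diag = cd_update(pset, [(ens_r, ens_f)], cfg)
        assert new.hbond.dist_on == before.hbond.dist_on
        assert new.hbond.dist_off == before.hbond.dist_off
        assert new.steric.radius == before.steric.radius
        assert new.steric.strength == before.steric.strength
        assert new.bonded.k_bond == before.bonded.k_bond
        for ctx in before.rama.grids:
            assert np.array_equal(new.rama.grids[ctx], before.rama.grids[ctx])
        # and the input pset object itself was not modified in place
        assert np.array_equal(pset.to_vector(), before.to_vector())


class TestTrainingLoop:
    def test_456_proteins_at_m12_give_38_minibatches(self):
        assert len(make_minibatches(456, 12)) == 38

    def test_step_size_schedule(self):
        # pass 0 and 1 at eps0; pass 2 decays by 1/4 -> step 2*38=76 onward
        cfg = CDConfig(step_size=1.0, passes_before_decay=2,
                       decay_factor=0.25, minibatch_size=12)
        eps = cfg.step_size
        seen = []
        for p in range(3):
            if p > 0 and p % cfg.passes_before_decay == 0:
                eps *= cfg.decay_factor
            for b in range(38):
                seen.append(eps)
        assert seen[75] == 1.0 and seen[76] == 0.25 and seen[77] == 0.25

    def test_single_protein_degenerates_to_plain_cd(self, helix8):
        cfg = _fast_config(sim_time=0.3)
        pset = ParameterSet.demo()
        final, history = training_loop(
            [helix8], pset, cfg, n_passes=2,
            model_factory=lambda ps: EnergyModel(ps, include_sidechain=False),
        )
        assert len(history) == 2
        assert history[0]["minibatch"] == 0
        assert np.isfinite(history[0]["mean_rmsd"])

    def test_resume_from_checkpoint_reproduces_uninterrupted_run(self, helix8):
        cfg = _fast_config(sim_time=0.3)
        pset = ParameterSet.demo()
        bb = lambda ps: EnergyModel(ps, include_sidechain=False)
        full, _ = training_loop(
            [helix8], pset, cfg, n_passes=2, model_factory=bb
        )
        mid, _ = training_loop(
            [helix8], pset, cfg, n_passes=1, model_factory=bb
        )
        resumed, _ = training_loop(
            [helix8], mid, cfg, n_passes=2, start_step=1, model_factory=bb
        )
        assert np.array_equal(full.to_vector(), resumed.to_vector())

    def test_empty_protein_list_raises(self):
        with pytest.raises(ValueError):
            training_loop([], ParameterSet.zeros(), _fast_config())
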