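"""Ensemble uncertainty, the 2×median selection rule, and the AL loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cspkit import Molecule, NMer
from cspkit.active_learning import (
    ALConfig,
    UncertaintyRecord,
    run_al,
    select_uncertain,
    uncertainty,
)
from cspkit.fixtures import FixtureSpec, make_fixture
from cspkit.nmer_sampling import ShellSpec, TetherSettings, enumerate_nmers, tethered_sampling
from cspkit.potentials import LabeledSample, train_ensemble, ensemble_predict


def _records(sigmas):
    return [UncertaintyRecord(i, s * math.sqrt(4), 4, s)
            for i, s in enumerate(sigmas)]


class TestSelectUncertain:
    def test_hand_median_case(self):
        # sigmas {1,2,3,10}: median 2.5, threshold 5 → only the 10 selected
        assert select_uncertain(_records([1.0, 2.0, 3.0, 10.0])) == [3]

    def test_all_equal_selects_nothing(self):
        assert select_uncertain(_records([2.0] * 6)) == []

    def test_single_record_selects_nothing(self):
        assert select_uncertain(_records([5.0])) == []

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_uncertain([])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=100.0,
                              allow_nan=False), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, sigmas):
        got = set(select_uncertain(_records(sigmas)))
        med = float(np.median(sigmas))
        expected = {i for i, s in enumerate(sigmas) if s > 2 * med}
        assert got == expected

    def test_order_invariance(self):
        sigmas = [0.3, 7.0, 1.1, 0.2, 9.5, 1.0]
        a = set(select_uncertain(_records(sigmas)))
        recs = _records(sigmas)
        b = set(select_uncertain(recs[::-1]))
        assert a == b


class TestUncertaintyRecord:
    def test_sigma_formula_enforced(self):
        with pytest.raises(ValueError):
            UncertaintyRecord(0, E_std=0.2, N=4, sigma=0.2)
        r = UncertaintyRecord(0, E_std=0.2, N=4, sigma=0.1)
        assert r.sigma == pytest.approx(0.1)

    def test_identical_models_zero_sigma(self, diatomic):
        mono = NMer([diatomic.reference["molecule"]])
        samples = [LabeledSample(mono, *diatomic.calculator.energy_forces(mono))
                   for _ in range(6)]
        model = train_ensemble(samples, seed=0, n_models=1)[0]
        rec = uncertainty([model] * 4, mono)
        assert rec.sigma == 0.0

    def test_far_dimer_sigma_scales_sqrt2(self, diatomic, rng):
        """Per-atom-additive models: doubling a molecule into a far-apart
        non-interacting dimer doubles E_std while N doubles → σ·√2."""
        mol = diatomic.reference["molecule"]
        mono = NMer([mol])
        far = NMer([mol, mol.translated([60.0, 0, 0])])
        samples = []
        for _ in range(12):
            frames = tethered_sampling(
                mono, diatomic.calculator,
                TetherSettings(n_steps=60, stride=20,
                               seed=int(rng.integers(2**31 - 1))))
            for f in frames:
                g = Molecule(mol.symbols, f, bonds=mol.bonds)
                samples.append(LabeledSample(
                    g, *diatomic.calculator.energy_forces(g)))
        ens = train_ensemble(samples, seed=1)
        r1 = uncertainty(ens, mono)
        r2 = uncertainty(ens, far)
        assert r2.N == 2 * r1.N
        assert r2.sigma == pytest.approx(math.sqrt(2) * r1.sigma, rel=1e-6)


@pytest.fixture(scope="module")
def al_setup():
    fx = make_fixture(FixtureSpec("rigid_diatomic_crystal"))
    teacher = fx.calculator
    nmers = enumerate_nmers(fx.structure, 3, 6, seed=1, shell=ShellSpec(0, 6.0))
    mono = [n for n in nmers if n.order == 1][0]
    dimers = [n for n in nmers if n.order == 2]
    trimers = [n for n in nmers if n.order == 3]

    def refit(nm, frame):
        out, off = [], 0
        for m in nm.molecules:
            out.append(Molecule(m.symbols, frame[off:off + len(m)],
                                bonds=m.bonds))
            off += len(m)
        return NMer(out, nm.total_charge)

    def diversify(pool, n_frames, seed):
        out, k = [], 0
        rng = np.random.default_rng(seed)
        while len(out) < n_frames:
            nm = pool[k % len(pool)]
            k += 1
            frames = tethered_sampling(nm, teacher, TetherSettings(
                k_tether=0.02, temperature=400.0, n_steps=300, stride=60,
                seed=int(rng.integers(2**31 - 1))))
            for fr in frames:
                out.append(refit(nm, fr))
                if len(out) >= n_frames:
                    break
        return out

    mono_geoms = diversify([mono], 40, 11)
    seed_set = [LabeledSample(g, *teacher.energy_forces(g))
                for g in mono_geoms]
    return {
        "teacher": teacher,
        "seed_set": seed_set,
        "dimers": diversify(dimers, 200, 22),
        "trimers": diversify(trimers, 100, 33),
        "holdout": diversify(dimers, 60, 44) + diversify(trimers, 40, 55),
    }


@pytest.fixture(scope="module")
def sparse_al_setup():
    """Sparse monomer seed set + broad dimer pool: the ensemble starts
    genuinely uncertain on dimers for every seed."""
    fx = make_fixture(FixtureSpec("rigid_diatomic_crystal"))
    teacher = fx.calculator
    nmers = enumerate_nmers(fx.structure, 2, 6, seed=1, shell=ShellSpec(0, 6.0))
    mono = [n for n in nmers if n.order == 1][0]
    dimers_base = [n for n in nmers if n.order == 2]

    def refit(nm, frame):
        out, off = [], 0
        for m in nm.molecules:
            out.append(Molecule(m.symbols, frame[off:off + len(m)],
                                bonds=m.bonds))
            off += len(m)
        return NMer(out, nm.total_charge)

    def diversify(pool, n_frames, seed, T, k):
        out, kk = [], 0
        rng = np.random.default_rng(seed)
        while len(out) < n_frames:
            nm = pool[kk % len(pool)]
            kk += 1
            frames = tethered_sampling(nm, teacher, TetherSettings(
                k_tether=k, temperature=T, n_steps=300, stride=60,
                seed=int(rng.integers(2**31 - 1))))
            for fr in frames:
                out.append(refit(nm, fr))
                if len(out) >= n_frames:
                    break
        return out

    mono_geoms = diversify([mono], 15, 11, T=400.0, k=0.02)
    return {
        "teacher": teacher,
        "seed_set": [LabeledSample(g, *teacher.energy_forces(g))
                     for g in mono_geoms],
        "dimers": diversify(dimers_base, 200, 22, T=600.0, k=0.01),
    }


def _holdout_mae(ens, holdout, teacher):
    return float(np.mean([
        abs(ensemble_predict(ens, g)[0] - teacher.energy(g))
        for g in holdout]))


class TestRunAL:
    def test_noop_when_nothing_selected(self, al_setup):
        # a pool of identical clusters has zero spread in sigma → no labels
        pool = [al_setup["dimers"][0]] * 10
        state = run_al(al_setup["teacher"], al_setup["seed_set"],
                       {2: pool}, ALConfig(), seed=0)
        assert state.history[0]["n_labelled"] == 0
        assert len(state.training_pool) == len(al_setup["seed_set"])

    def test_history_bookkeeping(self, al_setup):
        state = run_al(al_setup["teacher"], al_setup["seed_set"],
                       {2: al_setup["dimers"][:50],
                        3: al_setup["trimers"][:30]},
                       ALConfig(), seed=3)
        assert [h["order"] for h in state.history] == [2, 3]
        assert all(h["n_selected"] >= h["n_labelled"] for h in state.history)

    def test_reproducible_per_seed(self, al_setup):
        args = (al_setup["teacher"], al_setup["seed_set"],
                {2: al_setup["dimers"][:60]})
        s1 = run_al(*args, ALConfig(), seed=5)
        s2 = run_al(*args, ALConfig(), seed=5)
        assert s1.history == s2.history
        for m1, m2 in zip(s1.ensemble, s2.ensemble):
            for e in m1.weights:
                assert np.array_equal(m1.weights[e], m2.weights[e])

    def test_al_beats_random_selection(self, al_setup):
        """AL hold-out MAE below a same-budget random baseline on ≥7/10 seeds."""
        teacher = al_setup["teacher"]
        wins = 0
        for seed in range(10):
            state = run_al(teacher, al_setup["seed_set"],
                           {2: al_setup["dimers"], 3: al_setup["trimers"]},
                           ALConfig(), seed=seed)
            mae_al = _holdout_mae(state.ensemble, al_setup["holdout"], teacher)
            budget = [h["n_labelled"] for h in state.history]
            pool_r = list(al_setup["seed_set"])
            rng = np.random.default_rng(seed + 500)
            ens_r = train_ensemble(pool_r, seed=seed)
            for pool_o, nb in zip(
                    [al_setup["dimers"], al_setup["trimers"]], budget):
                idx = rng.choice(len(pool_o), size=min(nb, len(pool_o)),
                                 replace=False)
                for i in idx:
                    g = pool_o[i]
                    pool_r.append(LabeledSample(g, *teacher.energy_forces(g)))
                ens_r = train_ensemble(pool_r, seed=seed + 1000)
            if mae_al < _holdout_mae(ens_r, al_setup["holdout"], teacher):
                wins += 1
        assert wins >= 7

    def test_median_sigma_decreases_after_cycle(self, sparse_al_setup):
        """Labelling + retraining should not increase the pool's median σ
        (allowed to fail on ≤ 2 of 10 seeds).

        Probed with a deliberately sparse monomer seed set so that the
        pre-cycle ensemble is genuinely uncertain on dimers; once the median
        σ sits at the ensemble's subset-resampling noise floor the
        comparison no longer measures the learning mechanism.
        """
        teacher = sparse_al_setup["teacher"]
        pool = sparse_al_setup["dimers"]
        ok = 0
        for seed in range(10):
            state = run_al(teacher, sparse_al_setup["seed_set"], {2: pool},
                           ALConfig(), seed=seed)
            before = state.history[0]["median_sigma"]
            after = float(np.median([
                uncertainty(state.ensemble, g).sigma for g in pool]))
            ok += after <= before
        assert ok >= 8

    def test_teacher_failure_skips_sample(self, al_setup):
        class FlakyTeacher:
            def __init__(self, inner):
                self.inner = inner
                self.calls = 0

            def energy_forces(self, g):
                self.calls += 1
                if self.calls % 3 == 0:
                    raise RuntimeError("synthetic teacher failure")
                return self.inner.energy_forces(g)

        flaky = FlakyTeacher(al_setup["teacher"])
        msgs = []
        state = run_al(flaky, al_setup["seed_set"],
                       {2: al_setup["dimers"][:80]}, ALConfig(), seed=1,
                       log=msgs.append)
        h = state.history[0]
        assert h["n_labelled"] < h["n_selected"]
        assert msgs  # failures were logged
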