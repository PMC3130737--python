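"""Rigid-body redocking, matched-backbone binding energies, filtering."""

import numpy as np
import pytest

from msdesign.docking import (DockResult, RigidTransform, binding_energy,
                              dock_pert, filter_conformations,
                              split_state_spec)
from msdesign.optimizers import pack_exhaustive, pack_faster
from msdesign.packing import build_packing_problem
from msdesign.states import CorrespondenceMap, EntitySequence, StateSpec
from msdesign.structure import Residue, Structure


def _frame(up=True):
    a1 = np.array([0.0, 0.0, 1.0 if up else -1.0])
    a2 = np.array([1.0, 0.0, 0.0])
    return np.vstack([a1, a2, np.cross(a1, a2)])


def _tiny_dimer(gap=5.0, n=2, spacing=3.2):
    """Perfectly symmetric two-chain structure, no jitter."""
    residues = []
    for i in range(n):
        residues.append(Residue("A", i + 1, "A",
                                np.array([spacing * i, 0.0, 0.0]), _frame(True)))
    for i in range(n):
        residues.append(Residue("B", i + 1, "A",
                                np.array([spacing * i, 0.0, gap]), _frame(False)))
    return Structure(residues, name="tiny")


def _tiny_spec(n=2):
    entries = [(i + 1, "A", i + 1) for i in range(n)]
    entries += [(n + i + 1, "B", i + 1) for i in range(n)]
    return StateSpec("tiny", CorrespondenceMap(tuple(entries), 2 * n))


class TestRigidTransform:
    def test_identity(self):
        t = RigidTransform.identity()
        np.testing.assert_array_equal(t.rotation, np.eye(3))

    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(-np.eye(3), np.zeros(3))

    def test_compose_matches_sequential_application(self):
        rng = np.random.default_rng(0)
        t1 = RigidTransform.random(rng, 1.0, 10.0)
        t2 = RigidTransform.random(rng, 1.0, 10.0)
        x = rng.normal(size=3)
        seq = t2.rotation @ (t1.rotation @ x + t1.translation) + t2.translation
        np.testing.assert_allclose(t2.compose(t1).rotation @ x
                                   + t2.compose(t1).translation, seq)


class TestBindingEnergy:
    def test_separated_chains_bind_zero(self, params):
        dimer = _tiny_dimer(gap=25.0)
        spec = _tiny_spec()
        seq = EntitySequence("WWWW")

        def exhaustive(problem, seed):
            from msdesign.optimizers import PackerResult
            a = pack_exhaustive(problem)
            return PackerResult(a, a.energy)

        dg = binding_energy(spec, seq, dimer, packer=exhaustive, params=params)
        assert dg == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_homodimer_chain_energies_equal(self, params):
        dimer = _tiny_dimer()
        spec = _tiny_spec()
        seq = EntitySequence("WAWA")
        energies = {}
        for chain in ("A", "B"):
            sub = split_state_spec(spec, chain)
            mono = dimer.subset_chains([chain])
            problem = build_packing_problem(sub, seq, mono, params=params)
            energies[chain] = pack_faster(problem).energy
        assert energies["A"] == pytest.approx(energies["B"], abs=1e-12)

    def test_matches_exhaustive_recomputation(self, params):
        dimer = _tiny_dimer()
        spec = _tiny_spec()
        seq = EntitySequence("AWWA")
        dg_fast = binding_energy(spec, seq, dimer, packer=pack_faster,
                                 params=params)
        parts = []
        for chains in (["A", "B"], ["A"], ["B"]):
            sub = spec if len(chains) == 2 else split_state_spec(spec, chains[0])
            struct = dimer if len(chains) == 2 else dimer.subset_chains(chains)
            problem = build_packing_problem(sub, seq, struct, params=params)
            parts.append(pack_exhaustive(problem).energy)
        assert dg_fast == pytest.approx(parts[0] - parts[1] - parts[2], abs=1e-9)

    def test_requires_two_chains(self, params):
        mono = _tiny_dimer().subset_chains(["A"])
        with pytest.raises(ValueError, match="2 chains"):
            binding_energy(_tiny_spec(), EntitySequence("WWWW"), mono,
                           params=params)


class TestDockPert:
    def test_identity_perturbation_returns_input_energies(self, params):
        dimer = _tiny_dimer()
        spec = _tiny_spec()
        seq = EntitySequence("WAWA")
        res = dock_pert(spec, seq, dimer, n_traj=1, seed=0,
                        perturb=(0.0, 0.0), cycles=0, params=params)
        problem = build_packing_problem(spec, seq, dimer, params=params)
        assert res.total_energy == pytest.approx(pack_faster(problem).energy)
        assert res.binding_energy == pytest.approx(
            binding_energy(spec, seq, dimer, params=params))

    def test_more_trajectories_never_worse(self, het_system):
        spec = het_system.states["AB"]
        seq = EntitySequence("WWAGWAGA")
        common = dict(seed=4, perturb=(0.8, 3.0), cycles=3,
                      params=het_system.params)
        e1 = dock_pert(spec, seq, het_system.structures["AB"], n_traj=1,
                       **common).total_energy
        e4 = dock_pert(spec, seq, het_system.structures["AB"], n_traj=4,
                       **common).total_energy
        assert e4 <= e1

    def test_clash_relief(self, params):
        """A sequence whose side chains collide in the input conformation
        redocks to a lower binding energy; a translation grid is the oracle."""
        dimer = _tiny_dimer(gap=5.0)          # W-W contact needs ~6.3 A
        spec = _tiny_spec()
        seq = EntitySequence("WWWW")
        dg_input = binding_energy(spec, seq, dimer, params=params)
        best_grid = min(
            binding_energy(spec, seq,
                           dimer.transformed(np.eye(3), np.array([0, 0, dz]),
                                             chain_ids=["B"]),
                           params=params)
            for dz in np.linspace(0.0, 2.5, 26))
        assert best_grid < dg_input           # separating relieves the clash
        res = dock_pert(spec, seq, dimer, n_traj=6, seed=2,
                        perturb=(1.0, 4.0), cycles=10, params=params)
        assert res.binding_energy < dg_input
        assert res.binding_energy <= best_grid + 0.5

    def test_binding_energy_invariant_of_result(self, het_system):
        spec = het_system.states["AB"]
        seq = EntitySequence("WAGWAGWA")
        res = dock_pert(spec, seq, het_system.structures["AB"], n_traj=2,
                        seed=3, perturb=(0.5, 2.0), cycles=2,
                        params=het_system.params)
        recomputed = binding_energy(spec, seq, res.conformation,
                                    params=het_system.params)
        assert res.binding_energy == pytest.approx(recomputed, abs=1e-6)


class TestFilterConformations:
    @staticmethod
    def _result(dg, shift):
        conf = _tiny_dimer().transformed(np.eye(3), np.array([shift, 0.0, 0.0]))
        return DockResult(RigidTransform.identity(), dg, dg, conf)

    def test_energy_filter(self):
        confs = [self._result(-6.0, 0.0), self._result(-3.0, 5.0),
                 self._result(1.0, 10.0)]
        kept = filter_conformations(confs, dG_keep=-1.0, rms_min=0.0)
        assert len(kept) == 2

    def test_duplicate_dropped_by_diversity(self):
        confs = [self._result(-6.0, 0.0), self._result(-5.0, 0.0)]
        kept = filter_conformations(confs, dG_keep=-1.0, rms_min=0.5)
        assert len(kept) == 1

    def test_zero_rms_min_keeps_all_energy_passing(self):
        confs = [self._result(-6.0, 0.0), self._result(-5.0, 0.0),
                 self._result(-4.0, 0.0)]
        kept = filter_conformations(confs, dG_keep=-1.0, rms_min=0.0)
        assert len(kept) == 3

    def test_greedy_ascending_dg_order(self):
        # the second-best conformation is within rms_min of the best: dropped;
        # the third is far enough: kept
        confs = [self._result(-3.0, 0.2), self._result(-6.0, 0.0),
                 self._result(-4.0, 3.0)]
        kept = filter_conformations(confs, dG_keep=-1.0, rms_min=0.5)
        assert len(kept) == 2

    def test_idempotent(self):
        confs = [self._result(-6.0, s) for s in (0.0, 0.3, 2.0, 2.2, 8.0)]
        once = filter_conformations(confs, dG_keep=-1.0, rms_min=0.5)
        again_inputs = [DockResult(RigidTransform.identity(), -6.0, -6.0, c)
                        for c in once]
        twice = filter_conformations(again_inputs, dG_keep=-1.0, rms_min=0.5)
        assert len(twice) == len(once)
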