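"""Packing problems and the lazily-computed, memory-capped interaction graph."""

import numpy as np
import pytest

from msdesign.packing import (InteractionGraph, PackingProblem,
                              RotamerAssignment, build_packing_problem,
                              random_problem, total_energy, dump_problem)
from msdesign.states import EntitySequence


def _table_problem():
    """Two positions x two rotamers with a printed pair table."""
    m = np.array([[1.0, -2.0], [0.5, 4.0]])
    return PackingProblem(
        positions=[("A", 1), ("A", 2)],
        rotamers=[random_problem(1, 2, 0).rotamers[0]] * 2,
        one_body=[np.array([0.0, 3.0]), np.array([-1.0, 2.0])],
        neighbor_pairs={(0, 1)},
        pair_lookup=lambda i, j: m,
    )


class TestTotalEnergy:
    def test_hand_sum_2x2(self):
        p = _table_problem()
        # choice (0, 1): one_body 0.0 + 2.0, pair m[0,1] = -2.0
        assert total_energy(p, RotamerAssignment(np.array([0, 1]), 0.0)) \
            == pytest.approx(0.0 + 2.0 - 2.0)
        assert total_energy(p, RotamerAssignment(np.array([1, 0]), 0.0)) \
            == pytest.approx(3.0 - 1.0 + 0.5)

    def test_no_pairs_sums_one_body(self):
        p = _table_problem()
        p.neighbor_pairs = set()
        assert total_energy(p, RotamerAssignment(np.array([1, 1]), 0.0)) \
            == pytest.approx(3.0 + 2.0)

    def test_out_of_range_choice_raises(self):
        with pytest.raises(ValueError):
            total_energy(_table_problem(), RotamerAssignment(np.array([2, 0]), 0.0))


class TestBuildProblem:
    def test_designable_positions_carry_assigned_aa(self, het_system):
        spec = het_system.states["AB"]
        seq = EntitySequence("WGWGAAWW")
        problem = build_packing_problem(spec, seq, spec.get_structure(),
                                        params=het_system.params)
        by_key = dict(zip(problem.positions, problem.aas))
        for pos, chain, resnum in spec.correspondence.entries:
            assert by_key[(chain, resnum)] == seq[pos - 1]

    def test_secondary_positions_repack_wildtype(self, het_system):
        spec = het_system.states["AB"]
        problem = build_packing_problem(spec, het_system.wildtype_sequence,
                                        spec.get_structure(),
                                        params=het_system.params)
        struct = spec.get_structure()
        by_key = dict(zip(problem.positions, problem.aas))
        for key in spec.secondary_repack:
            assert by_key[key] == struct.residue(key).wildtype_aa

    def test_fixed_residue_contributes_to_one_body(self, line_structure, params):
        from msdesign.states import CorrespondenceMap, StateSpec
        spec = StateSpec("s", CorrespondenceMap(((1, "A", 1),), 1))
        with_fixed = build_packing_problem(spec, EntitySequence("W"),
                                           line_structure, params=params)
        from msdesign.structure import Structure
        smaller = Structure([r for r in line_structure.residues
                             if r.key != ("A", 2)])
        without = build_packing_problem(spec, EntitySequence("W"), smaller,
                                        params=params)
        assert ("A", 2) not in with_fixed.positions
        # the fixed residue's backbone sphere shifts the one-body energies
        assert not np.allclose(with_fixed.one_body[0], without.one_body[0])

    def test_missing_correspondence_target_names_residue(self, line_structure,
                                                         params):
        from msdesign.states import CorrespondenceMap, StateSpec
        spec = StateSpec("s", CorrespondenceMap(((1, "B", 99),), 1))
        with pytest.raises(KeyError, match="B99"):
            build_packing_problem(spec, EntitySequence("W"), line_structure,
                                  params=params)

    def test_dump_is_textual(self, het_system):
        spec = het_system.states["A"]
        problem = build_packing_problem(spec, het_system.wildtype_sequence,
                                        spec.get_structure(),
                                        params=het_system.params)
        text = dump_problem(problem)
        assert "background" in text and str(len(problem.positions[0][0])) not in ("",)
        assert len(text.splitlines()) == problem.n_positions + 3


class TestInteractionGraph:
    @staticmethod
    def _graph(ceiling=None):
        calls = []

        def compute(i, ai, j, aj):
            calls.append((i, ai, j, aj))
            rng = np.random.default_rng(abs(hash((i, ai, j, aj))) % 2**31)
            return rng.normal(size=(3, 3))

        return InteractionGraph(compute, memory_ceiling=ceiling), calls

    def test_second_access_cached(self):
        g, calls = self._graph()
        a = g.submatrix(("A", 1), "F", ("A", 2), "W")
        before = g.computed_count
        b = g.submatrix(("A", 1), "F", ("A", 2), "W")
        assert g.computed_count == before == 1
        np.testing.assert_array_equal(a, b)

    def test_swapped_arguments_return_transpose(self):
        g, _ = self._graph()
        m = g.submatrix(("A", 1), "F", ("A", 2), "W")
        mt = g.submatrix(("A", 2), "W", ("A", 1), "F")
        np.testing.assert_array_equal(mt, m.T)
        assert g.computed_count == 1

    def test_eviction_and_bitwise_recompute(self):
        bytes_per = 3 * 3 * 8
        g, _ = self._graph(ceiling=bytes_per)
        a1 = g.submatrix(("A", 1), "F", ("A", 2), "W").copy()
        g.submatrix(("A", 1), "F", ("A", 3), "W")      # evicts the first
        assert g.eviction_count == 1
        a2 = g.submatrix(("A", 1), "F", ("A", 2), "W")
        assert g.computed_count == 3                   # recomputed
        np.testing.assert_array_equal(a1, a2)

    def test_least_recently_accessed_evicted_first(self):
        bytes_per = 3 * 3 * 8
        g, _ = self._graph(ceiling=2 * bytes_per)
        ka = (("A", 1), "F", ("A", 2), "W")
        kb = (("A", 1), "F", ("A", 3), "W")
        kc = (("A", 1), "F", ("A", 4), "W")
        g.submatrix(*ka)
        g.submatrix(*kb)
        g.submatrix(*kc)       # A is the least recently accessed -> evicted
        assert ka not in g
        assert kb in g and kc in g

    def test_ceiling_honoured_after_every_access(self):
        bytes_per = 3 * 3 * 8
        g, _ = self._graph(ceiling=2 * bytes_per)
        for resnum in range(2, 12):
            g.submatrix(("A", 1), "F", ("A", resnum), "W")
            assert g.stored_bytes <= 2 * bytes_per

    def test_access_counter_monotone(self):
        g, _ = self._graph()
        counts = []
        for resnum in range(2, 6):
            g.submatrix(("A", 1), "F", ("A", resnum), "W")
            counts.append(g.access_counter)
        assert counts == sorted(counts) and len(set(counts)) == len(counts)


class TestEvictionTransparency:
    def test_packing_identical_under_tiny_ceiling(self, het_system):
        from msdesign.optimizers import pack_faster
        from msdesign.packing import InteractionGraph
        spec = het_system.states["AB"]
        struct = spec.get_structure()
        seq = EntitySequence("WAGWAGWA")
        results = []
        for ceiling in (None, 6 * 6 * 8):
            graph = InteractionGraph.for_structure(struct, het_system.params,
                                                   memory_ceiling=ceiling)
            problem = build_packing_problem(spec, seq, struct,
                                            params=het_system.params,
                                            graph=graph)
            res = pack_faster(problem, 0)
            results.append((res.energy, tuple(res.assignment.choice), graph))
        (e_unlimited, c_unlimited, _), (e_tiny, c_tiny, g_tiny) = results
        assert e_unlimited == e_tiny          # bit-identical energies
        assert c_unlimited == c_tiny
        assert g_tiny.eviction_count > 0      # the ceiling actually bit


def test_lazy_computation_saves_submatrices(het_system):
    """A design trajectory only computes the amino-acid pairs it sees."""
    from msdesign.ga import GAParams, MultistateEvaluator, run_ga
    from msdesign.fitness import parse_fitness_file
    from msdesign.optimizers import get_packer

    program = parse_fitness_file("STATE_VECTOR vAB\nFITNESS vmin(vAB)\n")
    evaluator = MultistateEvaluator(program, {"vAB": [het_system.states["AB"]]},
                                    get_packer("BMEC+sPR"), global_seed=0,
                                    params=het_system.params)
    params = GAParams(population=8, elite=4, generations=4,
                      allowed_aas=het_system.allowed_aas, seed=2)
    run_ga(evaluator, het_system.entity_length, params)
    stats = evaluator.graph_stats()
    spec = het_system.states["AB"]
    problem = build_packing_problem(spec, het_system.wildtype_sequence,
                                    spec.get_structure(), params=het_system.params)
    n_aas = len(het_system.allowed_aas)
    full = 0
    for i, j in problem.neighbor_pairs:
        ni = n_aas if problem.positions[i] in spec.correspondence.targets else 1
        nj = n_aas if problem.positions[j] in spec.correspondence.targets else 1
        full += ni * nj
    savings = 1.0 - stats["computed"] / full
    assert stats["computed"] < full
    assert savings > 0.0
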