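"""The fitness-definition language, entity functions, and the shipped
heterodimerization / orthogonal-interface fitness functions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from msdesign.fitness import (EntityFunctionDef, FitnessParseError,
                              evaluate_entity_function, evaluate_fitness,
                              fitness1_text, fitness2_text,
                              heterodimer_entity_function,
                              parse_entity_function_file, parse_fitness_file,
                              ral_fitness_text)
from msdesign.states import EntitySequence


class TestParser:
    def test_arithmetic(self):
        prog = parse_fitness_file("SCALAR_EXPRESSION x = 1 + 2*3\nFITNESS x\n")
        assert evaluate_fitness(prog, {}) == 7.0

    def test_min_over_states(self):
        prog = parse_fitness_file("STATE EA\nSTATE EB\nFITNESS min(EA, EB)\n")
        assert evaluate_fitness(prog, {"EA": -3.0, "EB": -7.0}) == -7.0

    def test_vmin_over_state_vector(self):
        prog = parse_fitness_file("STATE_VECTOR v\nFITNESS vmin(v)\n")
        assert evaluate_fitness(prog, {"v": [4.0, -2.0, 9.0]}) == -2.0

    def test_missing_fitness_rejected(self):
        with pytest.raises(FitnessParseError, match="no FITNESS"):
            parse_fitness_file("STATE EA\n")

    def test_two_fitness_lines_rejected(self):
        with pytest.raises(FitnessParseError, match="two FITNESS"):
            parse_fitness_file("STATE EA\nFITNESS EA\nFITNESS EA\n")

    def test_forward_reference_rejected(self):
        with pytest.raises(FitnessParseError, match="undefined identifier"):
            parse_fitness_file("SCALAR_EXPRESSION x = y + 1\nSTATE y\nFITNESS x\n")

    def test_syntax_error_carries_line_number(self):
        with pytest.raises(FitnessParseError, match="line 2"):
            parse_fitness_file("STATE EA\nSCALAR_EXPRESSION x = (EA\nFITNESS x\n")

    def test_unknown_command(self):
        with pytest.raises(FitnessParseError, match="unknown command"):
            parse_fitness_file("POWER_LEVEL x\nFITNESS x\n")

    def test_ite_division_pow_abs(self):
        prog = parse_fitness_file(
            "STATE e\n"
            "SCALAR_EXPRESSION b = ite(e < -20, 1, 0)\n"
            "SCALAR_EXPRESSION z = abs(e) / 2 + pow(2, 3) - b\n"
            "FITNESS z\n")
        assert evaluate_fitness(prog, {"e": -30.0}) == 15.0 + 8.0 - 1.0

    def test_vector_variable_and_expression(self):
        prog = parse_fitness_file(
            "STATE a\nSTATE b\n"
            "VECTOR_VARIABLE v = a b\n"
            "VECTOR_EXPRESSION w = v * 2 + 1\n"
            "FITNESS vmax(w)\n")
        assert evaluate_fitness(prog, {"a": 3.0, "b": -1.0}) == 7.0

    def test_unbound_state_raises(self):
        prog = parse_fitness_file("STATE EA\nFITNESS EA\n")
        with pytest.raises(KeyError, match="not bound"):
            evaluate_fitness(prog, {})


class TestEntityFunctions:
    def _identity(self, free=6, step=5.0, n=8):
        pairs = tuple((2 * k + 1, 2 * k + 2) for k in range(n))
        return EntityFunctionDef(((pairs, free, step),))

    def test_seven_of_eight_identical_pairs_scores_five(self):
        seq = EntitySequence("AAFFGGWWAAFFGGWA")   # pairs: 7 identical, 1 not
        assert evaluate_entity_function(self._identity(), seq) == 5.0

    def test_six_identical_pairs_clipped_to_zero(self):
        seq = EntitySequence("AAFFGGWWAAFFGAWA")   # exactly 6 identical
        assert evaluate_entity_function(self._identity(), seq) == 0.0

    def test_mutation_penalty_beyond_free(self):
        fn = EntityFunctionDef(
            mutation_penalties=(((1, 2, 3, 4, 5, 6, 7, 8), "AAAAAAAA", 5, 1.0),))
        assert evaluate_entity_function(fn, EntitySequence("WWWWWWWA")) == 2.0
        assert evaluate_entity_function(fn, EntitySequence("WWWWWAAA")) == 0.0

    def test_roundtrip_through_text_format(self):
        text = ("IDENTITY_PENALTY free 6 step 5 pairs 1:2 3:4 5:6 7:8 "
                "9:10 11:12 13:14 15:16\n"
                "MUTATION_PENALTY free 5 step 1 positions 1 3 5 7 9 11 13 15 "
                "wildtype FALAGLVW\n")
        fn = parse_entity_function_file(text)
        assert len(fn.identity_penalties) == 1
        assert fn.mutation_penalties[0][1] == "FALAGLVW"
        seq = EntitySequence("F" * 16)
        assert evaluate_entity_function(fn, seq) == \
            5.0 * (8 - 6) + 1.0 * (7 - 5)    # all pairs identical, 7 muts

    def test_malformed_line_rejected(self):
        with pytest.raises(ValueError, match="line 1"):
            parse_entity_function_file("IDENTITY_PENALTY free six step 5 pairs 1:2\n")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_permutation_covariance(self, seed):
        """Relabelling positions consistently leaves the score unchanged."""
        rng = np.random.default_rng(seed)
        L = 8
        seq = EntitySequence("".join(rng.choice(list("AGWFL"), L)))
        perm = rng.permutation(L)
        pairs = ((1, 2), (3, 4), (5, 6))
        fn = EntityFunctionDef(((pairs, 1, 2.0),))
        permuted_pairs = tuple((int(perm[p - 1]) + 1, int(perm[q - 1]) + 1)
                               for p, q in pairs)
        fn_perm = EntityFunctionDef(((permuted_pairs, 1, 2.0),))
        inv = np.empty(L, dtype=int)
        inv[perm] = np.arange(L)
        seq_perm = EntitySequence("".join(seq[inv[i]] for i in range(L)))
        assert evaluate_entity_function(fn, seq) == \
            evaluate_entity_function(fn_perm, seq_perm)


def _f1(w, eA, eB, eAB, eAA, eBB, seqconst=0.0):
    prog = parse_fitness_file(fitness1_text(w))
    prog.attach_entity_function("seqconst", EntityFunctionDef())
    env = {"vA": [eA], "vB": [eB], "vAB": [eAB], "vAA": [eAA], "vBB": [eBB]}
    return evaluate_fitness(prog, env, EntitySequence("AAAA")) + seqconst


def _f2(w2, eA, eB, eAB, eAA, eBB):
    prog = parse_fitness_file(fitness2_text(w2))
    prog.attach_entity_function("seqconst", EntityFunctionDef())
    env = {"vA": [eA], "vB": [eB], "vAB": [eAB], "vAA": [eAA], "vBB": [eBB]}
    return evaluate_fitness(prog, env, EntitySequence("AAAA"))


class TestHeterodimerFitness1:
    def test_worked_micro_case(self):
        """eAB=-100, eA=eB=-40, eAA=-85, eBB=-78, w=2:
        dGAB=-20, dGAA=min(-5,0)=-5, dGBB=min(+2,0)=0,
        gaps=(-20-(-5))+(-20-0)=-35, F=-100+2*(-35)=-170."""
        assert _f1(2.0, -40, -40, -100, -85, -78) == pytest.approx(-170.0)

    def test_negative_state_cap_invariance(self):
        """Raw homodimer binding of +3 and +1000 give identical fitness."""
        base = dict(w=2.0, eA=-40.0, eB=-40.0, eAB=-100.0, eBB=-78.0)
        f_plus3 = _f1(eAA=-80.0 + 3.0, **base)      # raw dGAA = +3
        f_plus1000 = _f1(eAA=-80.0 + 1000.0, **base)
        assert f_plus3 == f_plus1000

    def test_break_even_weight_is_half(self):
        """Trading 1 REU of heterodimer total energy for 1 REU of binding
        energy is fitness-neutral exactly at w = 0.5."""

        def delta(w):
            # homodimers held in the capped (raw dG > 0) region so the caps
            # are insensitive to the monomer shift
            f0 = _f1(w, -40, -40, -100, -70, -70)
            # +1 total energy, -1 binding energy (monomers up by 1 each)
            f1 = _f1(w, -39, -39, -99, -70, -70)
            return f1 - f0

        w_star = brentq(delta, 0.05, 5.0)
        assert w_star == pytest.approx(0.5, abs=1e-9)
        assert delta(0.6) < 0 < delta(0.4)   # above 0.5 favors the trade

    def test_strictly_decreasing_in_heterodimer_energy(self):
        f = [_f1(2.0, -40, -40, eAB, -85, -78) for eAB in (-100, -101, -102)]
        assert f[0] > f[1] > f[2]

    def test_flat_in_capped_region(self):
        f = [_f1(2.0, -40, -40, -100, -80 + raw, -78) for raw in (1.0, 5.0, 50.0)]
        assert f[0] == f[1] == f[2]


class TestHeterodimerFitness2:
    def test_saturation_below_minus_24(self):
        fixed = dict(w2=1.0, eA=-40.0, eB=-40.0, eAA=-95.0, eBB=-95.0)
        f_at = _f2(eAB=-80 - 24.0, **fixed)
        f_beyond = _f2(eAB=-80 - 30.0, **fixed)
        # below -24 the binding term stays put; only the total-energy term moves
        assert (f_beyond - f_at) == pytest.approx(-6.0)

    def test_homodimer_target_minus_12(self):
        """The homodimer penalty term reaches zero exactly at dG = -12."""
        fixed = dict(w2=1.0, eA=-40.0, eB=-40.0, eAB=-110.0, eBB=-95.0)
        f_ref = _f2(eAA=-80 - 12.0, **fixed)
        assert _f2(eAA=-80 - 11.0, **fixed) == pytest.approx(f_ref)
        assert _f2(eAA=-80 - 13.0, **fixed) == pytest.approx(f_ref + 1.0)

    def test_gate_disables_bonus_for_poor_heterodimers(self):
        # dGAB = -15 is above the -20 gate: homodimer term switched off
        gated = _f2(1.0, -40, -40, -95, -80 - 20.0, -80 - 20.0)
        also = _f2(1.0, -40, -40, -95, -80 - 25.0, -80 - 25.0)
        assert (also - gated) == pytest.approx(0.0)


def test_ral_fitness_per_backbone_monomers():
    prog = parse_fitness_file(ral_fitness_text(2.0))
    env = {"vAB": [-100.0], "vAC": [-90.0], "vAD": [-80.0],
           "vA_AB": [-40.0], "vA_AC": [-41.0], "vA_AD": [-39.0],
           "vB": [-30.0], "vC": [-31.0], "vD": [-29.0]}
    f = evaluate_fitness(prog, env)
    dGAB = -100 + 40 + 30
    dGAC = min(-90 + 41 + 31, 0)
    dGAD = min(-80 + 39 + 29, 0)
    assert f == pytest.approx(-100 + 2.0 * ((dGAB - dGAC) + (dGAB - dGAD)))


def test_heterodimer_entity_function_builder():
    wt = EntitySequence("WWAAWWAA")
    fn = heterodimer_entity_function(4, wildtype=wt, identity_free=2,
                                     identity_step=5.0, mutation_free=1,
                                     mutation_step=1.0)
    # all four pairs identical (two beyond free=2); one mutation per chain,
    # within the free allowance
    seq = EntitySequence("WWAAWWGG")
    assert evaluate_entity_function(fn, seq) == 5.0 * (4 - 2)
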