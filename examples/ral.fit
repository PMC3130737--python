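# Orthogonal-interface fitness: keep A binding B, stop A binding C and D.
# Binding energies compare each dimer with the monomers sharing the same
# backbone conformation, which requires modelling per-backbone copies of
# the A monomer (states A_AB, A_AC, A_AD).  Negative-state binding
# energies are capped at 0 as in the heterodimerization task.
STATE_VECTOR vAB
STATE_VECTOR vAC
STATE_VECTOR vAD
STATE_VECTOR vA_AB
STATE_VECTOR vA_AC
STATE_VECTOR vA_AD
STATE_VECTOR vB
STATE_VECTOR vC
STATE_VECTOR vD
SCALAR_EXPRESSION eAB = vmin(vAB)
SCALAR_EXPRESSION eAC = vmin(vAC)
SCALAR_EXPRESSION eAD = vmin(vAD)
SCALAR_EXPRESSION dGAB = eAB - vmin(vA_AB) - vmin(vB)
SCALAR_EXPRESSION dGAC = min(eAC - vmin(vA_AC) - vmin(vC), 0)
SCALAR_EXPRESSION dGAD = min(eAD - vmin(vA_AD) - vmin(vD), 0)
SCALAR_EXPRESSION gapAC = dGAB - dGAC
SCALAR_EXPRESSION gapAD = dGAB - dGAD
FITNESS eAB + 2 * (gapAC + gapAD)
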