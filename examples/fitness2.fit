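# Alternate heterodimerization fitness: the reward for heterodimer binding
# saturates at -24 REU (so total energy is not traded away for binding
# energy), and a gated bonus drives the homodimer binding energies up
# toward -12 REU.  The gate variable switches the homodimer bonus off for
# sequences whose heterodimer binding is not yet good (dGAB >= -20).
STATE_VECTOR vA
STATE_VECTOR vB
STATE_VECTOR vAB
STATE_VECTOR vAA
STATE_VECTOR vBB
ENTITY_FUNCTION seqconst
SCALAR_EXPRESSION eA = vmin(vA)
SCALAR_EXPRESSION eB = vmin(vB)
SCALAR_EXPRESSION eAB = vmin(vAB)
SCALAR_EXPRESSION eAA = vmin(vAA)
SCALAR_EXPRESSION eBB = vmin(vBB)
SCALAR_EXPRESSION dGAB = eAB - eA - eB
SCALAR_EXPRESSION dGAA = eAA - 2 * eA
SCALAR_EXPRESSION dGBB = eBB - 2 * eB
SCALAR_EXPRESSION bind = max(dGAB, -24)
SCALAR_EXPRESSION gatevar = ite(dGAB < -20, 1, 0)
SCALAR_EXPRESSION penAA = max(-12 - dGAA, 0)
SCALAR_EXPRESSION penBB = max(-12 - dGBB, 0)
FITNESS eAB + bind + 1.0 * gatevar * (penAA + penBB) + seqconst
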