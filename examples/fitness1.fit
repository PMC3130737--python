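# Heterodimerization fitness (gap form), gap weight 2.
#
# Five chemical species: monomers A and B, the desired AB heterodimer, and
# the undesired AA / BB homodimers.  Each STATE_VECTOR holds the packed
# energies of one species' conformational ensemble; binding energies use
# the best (lowest) energy of each ensemble, and the negative-state binding
# energies are capped at 0 before entering the gaps.
STATE_VECTOR vA
STATE_VECTOR vB
STATE_VECTOR vAB
STATE_VECTOR vAA
STATE_VECTOR vBB
ENTITY_FUNCTION seqconst          # see heterodimer.entityfunc
SCALAR_EXPRESSION eA = vmin(vA)
SCALAR_EXPRESSION eB = vmin(vB)
SCALAR_EXPRESSION eAB = vmin(vAB)
SCALAR_EXPRESSION eAA = vmin(vAA)
SCALAR_EXPRESSION eBB = vmin(vBB)
SCALAR_EXPRESSION dGAB = eAB - eA - eB
SCALAR_EXPRESSION dGAA = min(eAA - 2 * eA, 0)
SCALAR_EXPRESSION dGBB = min(eBB - 2 * eB, 0)
SCALAR_EXPRESSION gapAA = dGAB - dGAA
SCALAR_EXPRESSION gapBB = dGAB - dGBB
FITNESS eAB + 2 * (gapAA + gapBB) + seqconst
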