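# Methods

This note documents the models and procedures implemented in `msdesign`,
the parameters that matter, and the design choices made where the design
was genuinely open. Energies are quoted in REU (the arbitrary unit of the
toy score function).

## The bead-rotamer model

Every residue contributes a fixed *backbone sphere* at its C-alpha anchor
(radius 1.7 Å) and, if packable, a set of discrete *rotamers*: one
side-chain sphere per rotamer, placed along an orientation axis of the
residue's local frame at

```
radius(aa) = 1.0 + 0.25 * c(aa)^(1/3)        [Å]
offset(aa) = 0.5 + 0.35 * c(aa)^(1/2)        [Å]
```

where `c(aa)` is the side chain's heavy-atom count; glycine (`c = 0`) gets
a single rotamer at the anchor. Hydrophobicity is the Kyte–Doolittle index
normalized by 4.5. Two rotamer spheres interact through a 12-6 well,

```
E(d) = eps_ij * [(sigma/d)^12 - 2 (sigma/d)^6],   d <= cutoff, else 0
sigma  = r_i + r_j
eps_ij = eps0 * (1 + h_i * h_j)
```

so the minimum is exactly `-eps_ij` at sphere contact. Defaults:
`eps0 = 0.5` REU, `cutoff = 6.0` Å.

**Orientations.** Six directions per rotamer: straight along the
C-beta axis plus five on a 60° cone around it. Orientations are
deliberately confined to the C-beta side of the backbone: with a full
±axis set a side chain could vacate an interface sideways at no cost,
which real side-chain volume forbids, and packing would carry no
information about sequence.

**Backbone interactions.** A rotamer interacts with the backbone spheres
of its *own* chain through the full well — this burial term is what makes
the backbone-minimum-energy conformation (BMEC) nontrivial — but backbone
spheres act on other chains' rotamers, and on each other, only through the
repulsive branch of the well (excluded volume). An attractive backbone
funnel would otherwise dominate chain–chain association identically for
every sequence, and no binding-specificity design would be possible in
principle.

**Multistate safeguards.** In multistate mode (the default) the
backbone-collision filter ("bump check", threshold 5 REU when enabled) is
forced off and the full orientation set is always built, so the rotamer
set available for a given (amino acid, local geometry) is identical in
every state sharing that geometry. This removes the missing-rotamer
failure mode in which a rotamer present only in a positive state
masquerades as binding energy.

## Packing

A packing problem holds, per packable position, the rotamers of a single
amino acid (the threaded sequence fixes identities): one-body energies
(rotamer vs. all backbone spheres), sparse pairwise terms between neighbor
positions, and a constant background (backbone–backbone). Non-packable
residues are reduced to their backbone spheres.

Pair-energy submatrices are computed on first access and cached in an
interaction graph keyed by (position, amino acid) pairs; a design
trajectory therefore only pays for the amino-acid pairs its sequences
co-locate. An optional byte ceiling (8 bytes per stored energy) is
enforced by evicting the submatrix whose most recent access lies furthest
in the past (binary heap of access orders); eviction only costs
recomputation and never changes results.

Optimizers: BMEC; quench (strictly-downhill sweeps to a fixed point);
BMEC+sPR (FASTER-style single-residue perturbation/relaxation, relaxing at
most the 10 neighbors with greatest-magnitude interaction with the
perturbed rotamer, ≤10 relaxation passes, ≤30 sweeps, strict-decrease
acceptance); the standard annealer (19 geometric temperatures from kT 100
to 0.3, reheat when the final energy of an iteration is not at least 1 REU
below the mean of the previous three, best-restore + quench at the end);
the multi-cool annealer (20 temperatures from kT 10 to 0.2 with three
quench-and-restore operations per temperature — sixty in total — keeping
the 10 best quenched assignments, then six trajectories from kT 0.25 to
0.05 over 10 temperatures started from the best six in energy order); and
`N x (p% SimA + sPR)` hybrids (shortened annealing, then sPR, best over N
restarts with per-restart derived seeds). Moves per temperature default to
5·R, R the total rotamer count — the counts are configurable because no
canonical values exist for the toy. All stochastic packers are
deterministic in (problem, seed); ties break to the lowest index
everywhere. An exhaustive enumerator (broadcast over the full assignment
tensor, ≤10⁷ states, lexicographic tie-break) serves as the GMEC oracle.

Energy bookkeeping is incremental with a full recomputation audit every
10⁴ substitutions to bound drift.

## States, threading, and the order-independence contract

A state is a structure, a correspondence map (entity position → residues;
one position may map to several residues, which is how homodimer states
thread one half of the sequence onto both chains), a secondary repack set
(repack at wild type, never design), and a replicate count (replicated
packing takes the best energy, useful for stochastic packers on states
whose energies must be accurate). There is no distributed runtime: every
random stream derives from `stable_mix(global seed, state name, sequence,
replicate)`, so any work partitioning or evaluation order gives
bit-identical results — the contract a parallel implementation would have
to honour.

## The fitness language

Seven commands (`STATE`, `STATE_VECTOR`, `SCALAR_EXPRESSION`,
`VECTOR_VARIABLE`, `VECTOR_EXPRESSION`, `ENTITY_FUNCTION`, `FITNESS`);
expressions support `+ - * /`, unary minus, parentheses, binary
`min`/`max`, vector reductions `vmin`/`vmax`, `abs`, `pow`, and
`ite(cond, a, b)` with comparisons — division and `ite` exist for gating
variables. Identifiers must be defined on earlier lines (acyclic by
construction); exactly one `FITNESS`; lower is better.

The shipped heterodimerization fitness functions (see `examples/`):

* fitness-1: `F = eAB + w * [(dGAB − min(dGAA,0)) + (dGAB − min(dGBB,0))] + Eseq`.
  Capping the negative-state binding energies at 0 prevents the search
  from piling physically meaningless collisions into one homodimer; the
  cap point is where the rigid-docked model of a complex stops being
  valid. The algebra implies a break-even at `w = 0.5` between 1 REU of
  heterodimer total energy and 1 REU of heterodimer binding energy; all
  weights above it favour the trade.
* fitness-2: `F = eAB + max(dGAB, −24) + w2·b·[max(−12 − dGAA, 0) + max(−12 − dGBB, 0)] + Eseq`
  with gate `b = ite(dGAB < −20, 1, 0)`. The saturating reward stops the
  total-for-binding trade below −24 REU, the penalty drives homodimer
  binding up toward −12 REU, and the gate avoids rewarding homodimer
  destabilization for sequences whose heterodimer is not yet good (the
  −20 gate value is a package choice; nothing pins it beyond being
  between the saturation point and zero).
* Ral-style orthogonal fitness: per-backbone monomer states (`A_AB`,
  `A_AC`, `A_AD`) so every binding energy compares structures with
  matched backbones.

Entity functions score sequence alone: `IDENTITY_PENALTY` (k identical
position pairs beyond `free` cost `step` REU each) and `MUTATION_PENALTY`
(mutations beyond `free` per chain cost `step` each). The
heterodimerization defaults are free 6 of 8 pairs at 5 REU and free 5
mutations at 1 REU; at smaller interface sizes the pipeline keeps the
*penalised headroom* fixed (identity free = pairs − 2, mutation free =
pairs − 3) so the constraints stay binding.

## Genetic algorithm

Population 100, elite 50 carried unchanged, 98 % of proposals are
single-point mutants of uniformly chosen elite parents and 2 % are uniform
per-position crossovers of two distinct members of the previous
population; generations default to 15·L (the constant is a package choice
— only the linear dependence on L is given). Duplicate sequences are
allowed; fitness is memoised by sequence text, which is
semantics-preserving because packer seeds depend on the sequence text and
not on evaluation order. The initial population is random over the
allowed alphabet, optionally seeded with given sequences (the pipeline
seeds the wild type).

## Docking and the iterative protocol

`dock_pert` is a perturb-and-refine rigid-body protocol: each trajectory
splits and repacks the chains (in this model a bookkeeping no-op, since
rotamers are re-optimized from scratch at every energy evaluation),
applies a random perturbation to the second (mobile) chain — per-axis
normal translation, random-axis rotation about the mobile centroid — then
runs Monte-Carlo refinement cycles (perturbation scaled by 0.2, repack,
Metropolis at kT 0.8); the best of `n_traj` trajectories by total energy
is returned. Function defaults are 3 Å / 8° / 50 cycles / 50
trajectories. Binding energies are always matched-backbone: bound energy
minus the separately packed chains extracted from the same conformation;
chains separated beyond the interaction cutoff therefore bind exactly 0.

Conformation filtering keeps docked negatives with binding energy at or
below `dG_keep` (default −1 REU), then greedily (ascending binding energy)
enforces mutual C-alpha RMS *without superposition* of at least `rms_min`
(default 0.5 Å). Both thresholds are configurable; nothing pins their
exact values.

A *round* of the iterative protocol runs one GA trajectory per (gap
weight, positive conformation) pair, records for each reported design the
binding energy of every species as the design saw it (minimum over the
ensemble) and after redocking, and defines the round error as their signed
difference (the absolute mean is reported alongside). Filtered redocked
negatives join the ensembles for the next round, so ensemble sizes are
non-decreasing and the error shrinks as the negatives' reachable
conformations become visible to the design.

## The synthetic systems

Scaffolds are arcs of anchors (radius 15 Å, spacing 3.0 Å) with frames
pointing across the interface; dimers are two face-to-face arcs. Three
constructions give the interface genuine, dockable shape complementarity:

* the cross-chain anchor gap at each packable pair equals the contact
  distance of the two wild-type side chains — the input pose is a
  rigid-body optimum for the wild-type sequence, the way a crystal
  structure is;
* the interface bows gently in z (curvature 0.015 Å⁻¹), penalizing rigid
  slides along the chain direction;
* the 3.0 Å spacing is tight enough that side chains cannot interdigitate
  between the partner chain's side chains.

Per-coordinate jitter (±0.15 Å, seeded) makes systems differ across
seeds. The heterodimerization system has five species (A, B, AB, AA, BB)
on one shared backbone, odd entity positions threading chain A and even
chain B; the orthogonal system has partners B, C, D with distinct
wild-type motifs and per-backbone A-monomer copies. The design tasks use
`eps0 = 2.0` and `cutoff = 4.5` Å: the constraint magnitudes (5 REU per
identical pair, 1 REU per mutation) presuppose binding energies in the
tens of REU, and with the 6 Å default cutoff over a 3 Å-spaced interface
the sum of long-range tails rewards any dense chain arrangement
independent of sequence. The design alphabet is `A G W` — three clearly
separated sphere sizes. Well widths scale with sigma, so letters of
near-identical size are energetically interchangeable, and an alphabet
containing them would let homodimer-like sequences slip past the identity
penalty without paying any packing cost.

What the generator does *not* emulate: backbone flexibility, real rotamer
statistics, electrostatics/hydrogen bonding, and any torsional coupling
between neighbouring residues. Tests passing on these systems show the
*algorithms* behave as specified (optimality bounds, determinism,
protocol-level trends); they say nothing about accuracy on real proteins.

## Problem sizes used by the test suite

The oracle suite uses 200 random instances of 5 positions × 4 rotamers
(exhaustive enumeration is exact there). The iterative-protocol checks run
the heterodimerization system with 4 designable positions per chain, GA
population 16 / elite 8 / 8 generations, docking with 8 trajectories × 12
cycles at 0.8 Å / 3° perturbations, 3 rounds — small enough to run in a
couple of minutes while preserving every mechanism (ensemble expansion,
capping, sequence constraints, matched-backbone energies).

## Known limitations

* The toy energy's specificity channel is sphere-size complementarity;
  margins between designs are a few REU, so protocol-level comparisons
  (e.g. multistate vs. single-state) are qualitative, not quantitative.
* `dock_pert` is local: it refines around the input conformation and can
  miss remote rigid minima; the iterative protocol compensates by
  accumulating conformations over rounds.
* The exhaustive oracle is limited to ~10⁷ assignments; larger problems
  are checked against the consensus (best-of-pool) energy instead.
* The fitness language evaluates programs interpretively; it is meant for
  combining a few dozen state energies, not as a numeric DSL.
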