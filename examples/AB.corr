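# Correspondence file for the AB heterodimer state.
# Format: one entry per line, "entity_position residue_number chain".
# Odd entity positions thread onto chain A, even onto chain B; e.g.
# "residue 24 on chain A takes its identity from position 3".
ENTITY_LENGTH 16
1 21 A
3 24 A
5 25 A
7 28 A
9 32 A
11 44 A
13 46 A
15 48 A
2 21 B
4 24 B
6 25 B
8 28 B
10 32 B
12 44 B
14 46 B
16 48 B
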