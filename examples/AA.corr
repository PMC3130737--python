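# Correspondence file for the AA homodimer state: both chains take their
# identity from the odd entity positions (one entity position may map to
# several residues).
ENTITY_LENGTH 16
1 21 A
3 24 A
5 25 A
7 28 A
9 32 A
11 44 A
13 46 A
15 48 A
1 21 B
3 24 B
5 25 B
7 28 B
9 32 B
11 44 B
13 46 B
15 48 B
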