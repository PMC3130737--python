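# Secondary resfile: boundary residues repacked at wild-type identity but
# never designed.  Format: "chain residue_number".
A 22
A 29
B 22
B 29
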