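# State-vector list file: one state per line,
# "structure_file correspondence_file secondary_resfile".
AB.txt AB.corr AB.secondary
AA.txt AA.corr AB.secondary
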