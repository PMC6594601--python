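# Vernacular Italian tokens encountered in 16th-century specimen labels;
# a name containing one of these is flagged vernacular even without "vulgo".
# Normalized orthography (u/v, i/j, y/i unified).
iaro
chiaro
barba
erba
ranoncolo
bolognese
fiore
giglio
cipolla
finocchio
saluatica
domestica
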