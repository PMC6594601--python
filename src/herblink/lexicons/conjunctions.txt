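# Linking words between alternative names on one specimen label.
# Their presence is a collection-distinguishing stylistic feature;
# they are removed from tokens and flagged.
seu
sive
vel
et
over
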