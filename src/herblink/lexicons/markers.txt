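# Generic qualifier words inside period plant names. These signal usage
# ("called X by some") rather than plant identity and are stripped from the
# comparable token sequence. Multi-word phrases are matched before
# tokenization. One entry per line; "#" starts a comment.
vulgo
quibusdam
ab aliquibus
aliquibus
alius
aliud
species
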