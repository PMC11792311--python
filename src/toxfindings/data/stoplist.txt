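# Surfaces dropped as false positives after tagging (one per line).
# These generic words match lexicon entries only in pathological contexts.
level
levels
value
values
data
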