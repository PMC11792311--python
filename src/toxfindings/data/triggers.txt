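# Treatment-relatedness trigger phrases, one per line, case-insensitive.
treatment-related
treatment related
compound-related effect
compound-related
attributable to treatment
related to treatment
test article-related
test article related
treatment-induced
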