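surface	preferred_term	code	category	source	domain_code
increase	Increase	M-INC	MANIFESTATION	INTERNAL	UNASSIGNED
increases	Increase	M-INC	MANIFESTATION	INTERNAL	UNASSIGNED
increased	Increase	M-INC	MANIFESTATION	INTERNAL	UNASSIGNED
higher	Increase	M-INC	MANIFESTATION	INTERNAL	UNASSIGNED
elevated	Increase	M-INC	MANIFESTATION	INTERNAL	UNASSIGNED
elevation	Increase	M-INC	MANIFESTATION	INTERNAL	UNASSIGNED
elevations	Increase	M-INC	MANIFESTATION	INTERNAL	UNASSIGNED
decrease	Decrease	M-DEC	MANIFESTATION	INTERNAL	UNASSIGNED
decreases	Decrease	M-DEC	MANIFESTATION	INTERNAL	UNASSIGNED
decreased	Decrease	M-DEC	MANIFESTATION	INTERNAL	UNASSIGNED
lower	Decrease	M-DEC	MANIFESTATION	INTERNAL	UNASSIGNED
reduced	Decrease	M-DEC	MANIFESTATION	INTERNAL	UNASSIGNED
reduction	Decrease	M-DEC	MANIFESTATION	INTERNAL	UNASSIGNED
reductions	Decrease	M-DEC	MANIFESTATION	INTERNAL	UNASSIGNED
diminished	Decrease	M-DEC	MANIFESTATION	INTERNAL	UNASSIGNED
less	Decrease	M-DEC	MANIFESTATION	INTERNAL	UNASSIGNED
alteration	Alteration	M-ALT	MANIFESTATION	INTERNAL	UNASSIGNED
alterations	Alteration	M-ALT	MANIFESTATION	INTERNAL	UNASSIGNED
altered	Alteration	M-ALT	MANIFESTATION	INTERNAL	UNASSIGNED
change	Alteration	M-ALT	MANIFESTATION	INTERNAL	UNASSIGNED
changed	Alteration	M-ALT	MANIFESTATION	INTERNAL	UNASSIGNED
changes	Alteration	M-ALT	MANIFESTATION	INTERNAL	UNASSIGNED
male	Male	SEX-M	SEX	INTERNAL	UNASSIGNED
males	Male	SEX-M	SEX	INTERNAL	UNASSIGNED
female	Female	SEX-F	SEX	INTERNAL	UNASSIGNED
females	Female	SEX-F	SEX	INTERNAL	UNASSIGNED
both sexes	Both	SEX-B	SEX	INTERNAL	UNASSIGNED
males and females	Both	SEX-B	SEX	INTERNAL	UNASSIGNED
both males and females	Both	SEX-B	SEX	INTERNAL	UNASSIGNED
both	Both	SEX-B	SEX	INTERNAL	UNASSIGNED
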