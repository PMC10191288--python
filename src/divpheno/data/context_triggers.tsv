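phrase	category	direction	max_scope
no	pre_negation	forward	10
no evidence of	pre_negation	forward	10
no evidence for	pre_negation	forward	10
no sign of	pre_negation	forward	10
no signs of	pre_negation	forward	10
no new	pre_negation	forward	10
without	pre_negation	forward	10
without evidence of	pre_negation	forward	10
denies	pre_negation	forward	10
denied	pre_negation	forward	10
negative for	pre_negation	forward	10
not	pre_negation	forward	10
never had	pre_negation	forward	10
free of	pre_negation	forward	10
absence of	pre_negation	forward	10
fails to reveal	pre_negation	forward	10
cannot see	pre_negation	forward	10
rules out	pre_negation	forward	10
unremarkable for	pre_negation	forward	10
ruled out	post_negation	backward	5
was ruled out	post_negation	backward	5
is ruled out	post_negation	backward	5
unlikely	post_negation	backward	5
not seen	post_negation	backward	5
was excluded	post_negation	backward	5
has resolved	post_negation	backward	5
not identified	post_negation	backward	5
no increase	pseudo_negation	forward	10
no change	pseudo_negation	forward	10
no further	pseudo_negation	forward	10
not ruled out	pseudo_negation	forward	10
cannot be ruled out	pseudo_negation	forward	10
not necessarily	pseudo_negation	forward	10
gram negative	pseudo_negation	forward	10
without difficulty	pseudo_negation	forward	10
but	termination	forward	0
however	termination	forward	0
although	termination	forward	0
except	termination	forward	0
aside from	termination	forward	0
apart from	termination	forward	0
nevertheless	termination	forward	0
yet	termination	forward	0
if	hypothetical	forward	10
rule out	hypothetical	forward	10
r/o	hypothetical	forward	10
to rule out	hypothetical	forward	10
evaluate for	hypothetical	forward	10
assess for	hypothetical	forward	10
screen for	hypothetical	forward	10
possible	hypothetical	forward	10
question of	hypothetical	forward	10
suspicion of	hypothetical	forward	10
concern for	hypothetical	forward	10
versus	hypothetical	forward	10
family history of	experiencer_other	forward	10
family history	experiencer_other	forward	10
fh of	experiencer_other	forward	10
mother	experiencer_other	forward	10
father	experiencer_other	forward	10
brother	experiencer_other	forward	10
sister	experiencer_other	forward	10
grandmother	experiencer_other	forward	10
grandfather	experiencer_other	forward	10
maternal	experiencer_other	forward	10
paternal	experiencer_other	forward	10
history of	historical	forward	10
h/o	historical	forward	10
hx of	historical	forward	10
past medical history of	historical	forward	10
pmh of	historical	forward	10
known history of	historical	forward	10
status post	historical	forward	10
previous	historical	forward	10
prior	historical	forward	10
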