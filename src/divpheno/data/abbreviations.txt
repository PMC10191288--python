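# Tokens that may legitimately precede a period mid-sentence; the sentence
# splitter will not break after these (case-insensitive, stored without the
# trailing period).
dr
mr
mrs
ms
prof
st
vs
fig
e.g
i.e
approx
pt
wnl
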