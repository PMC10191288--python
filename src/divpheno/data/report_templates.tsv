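slot	template
affirmed_osis	Multiple diverticula in the sigmoid colon.
affirmed_osis	Scattered diverticula were seen in the descending colon.
affirmed_osis	Sigmoid diverticulosis noted.
affirmed_osis	Moderate diverticulosis of the left colon.
affirmed_itis	Findings consistent with acute diverticulitis.
affirmed_itis	Acute uncomplicated diverticulitis of the sigmoid colon.
affirmed_itis	Sigmoid wall thickening with fat stranding consistent with diverticulitis.
negated	No diverticula or masses identified.
negated	No evidence of diverticulosis.
negated	No evidence of diverticulitis.
negated	No diverticula were seen.
neutral	The colonic mucosa is normal throughout.
neutral	Unremarkable examination of the entire colon.
neutral	Normal appearing mucosa; retroflexion in the rectum was normal.
neutral	The terminal ileum appeared normal.
distractor_hypothetical	Evaluate for diverticulitis if symptoms recur.
distractor_hypothetical	Referred to rule out diverticulitis.
distractor_family	Family history of diverticulitis in a first-degree relative.
distractor_family	Mother had diverticulosis.
filler	The preparation was adequate.
filler	The patient tolerated the procedure well.
filler	Scope was advanced to the cecum.
filler	Withdrawal time was 8 minutes.
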