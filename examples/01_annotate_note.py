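"""Annotate a colonoscopy note: find diverticular mentions and assert them.

Each mention of the diverticul* family is located and labelled affirmed,
negated, hypothetical, other-experiencer, or historical by the trigger/scope
rules; the document summary says whether the note as a whole is positive.
"""

from divpheno import annotate, summarize_document

NOTE = (
    "The prep was adequate. Scattered diverticula were seen in the sigmoid "
    "colon. No evidence of diverticulitis. Family history of diverticulitis "
    "in a first-degree relative."
)

mentions = annotate(NOTE)
for m in mentions:
    print(f"  [{m.char_start:3d}:{m.char_end:3d}] {m.matched_text:15s} -> {m.assertion.value}")

doc = summarize_document(mentions)
print(f"document positive for diverticulosis: {doc.positive_diverticulosis}")
print(f"document positive for diverticulitis: {doc.positive_diverticulitis}")

# The affirmed 'diverticula' makes the note diverticulosis-positive; the
# negated and family-history 'diverticulitis' mentions do not count, so the
# note is diverticulitis-negative.
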