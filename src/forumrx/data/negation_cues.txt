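# One negation cue per line; multi-word cues allowed. A cue within the five
# tokens preceding a drug mention (same sentence) marks the mention negated.
not
no
never
didn't
didnt
don't
dont
won't
wont
can't
cant
cannot
couldn't
couldnt
haven't
havent
without
declined
refused
denied
refusing
declining
no longer
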