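# Scope terminators: if one of these appears between a negation cue and the
# mention, the cue's scope is closed and the mention is NOT negated.
but
however
although
though
except
yet
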