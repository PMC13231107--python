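# Contextual cue rules: cue_pattern	cue_class	direction	scope_terminators	max_scope_tokens
# Directions: forward = cue scopes over following tokens, backward = preceding, bidirectional = both.
denies	negation	forward	but;however;although;except	10
denied	negation	forward	but;however;although;except	10
does not	negation	forward	but;however;although;except	10
negative for	negation	forward	but;however;although;except	10
without	negation	forward	but;however;although;except	5
history of	historical	forward	but;however;although	10
previously	historical	forward	but;however;although	10
in the past	historical	backward	but;however;although	10
years ago	historical	backward	but;however;although	10
formerly	historical	forward	but;however;although	10
mother	experiencer	forward	but;however;although	10
father	experiencer	forward	but;however;although	10
husband	experiencer	forward	but;however;although	10
wife	experiencer	forward	but;however;although	10
daughter	experiencer	forward	but;however;although	10
son	experiencer	forward	but;however;although	10
brother	experiencer	forward	but;however;although	10
sister	experiencer	forward	but;however;although	10
applying for	hypothetical	forward	but;however;although	10
considering	hypothetical	forward	but;however;although	10
plans to	hypothetical	forward	but;however;although	10
recommended	hypothetical	forward	but;however;although	10
discussed	hypothetical	forward	but;however;although	10
possible	uncertainty	forward	but;however;although	5
possibly	uncertainty	forward	but;however;although	5
unclear if	uncertainty	forward	but;however;although	10
may have	uncertainty	forward	but;however;although	10
questionable	uncertainty	forward	but;however;although	5
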