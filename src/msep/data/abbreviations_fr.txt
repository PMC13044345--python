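# Protected French clinical abbreviations: a period inside these tokens
# never ends a sentence.
M.
Mme.
Mlle.
Dr.
Pr.
cf.
ex.
p.ex.
env.
etc.
vol.
av.
art.
max.
min.
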