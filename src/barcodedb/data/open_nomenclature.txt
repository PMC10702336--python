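# Open-nomenclature qualifiers stripped during name cleaning.
# One token per line; matching is case-insensitive and tolerant of a
# missing trailing period ("cf" matches "cf.").  Everything after the
# first qualifier token is dropped, because the identification of the
# following name parts was uncertain.
aff.
cf.
cff.
sp.
spp.
nr.
prope
gr.
s.l.
s.s.
indet.
?
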