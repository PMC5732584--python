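# Negation word list used by the structural features of Set 1.
not
no
never
n't
cannot
cant
can't
dont
don't
won't
wont
isn't
isnt
aren't
arent
wasn't
wasnt
weren't
werent
couldn't
couldnt
shouldn't
shouldnt
wouldn't
wouldnt
didn't
didnt
doesn't
doesnt
ain't
aint
nothing
nobody
nowhere
neither
nor
without
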