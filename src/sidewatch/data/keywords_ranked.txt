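# Reconstructed ranked suicide-related keyword list (top of a tf-idf
# contrast ranking over ideation vs non-ideation web-forum text).
# One phrase per line, rank order.  Curated with keywords_removals.txt
# to the final 62-entry keyword lexicon.
kill myself
want to die
end my life
suicidal
suicide
asleep and never wake
don't want to exist
want to end it
end it all
want to disappear
my life is pointless
isn't worth living
don't want to try anymore
to live any more
can't go on
can't take it anymore
better off dead
better off without me
tired of living
don't want to be here
ready to die
wish i was dead
wish i were dead
take my own life
end the pain
no reason to live
nothing to live for
want it to be over
can't do this anymore
done with life
give up on life
never wake up
sleep forever
overdose
self harm
selfharm
cut myself
hurt myself
hate my life
life is meaningless
no point in living
want to be dead
die in my sleep
disappear forever
say goodbye forever
end it tonight
put an end to it
not worth living
worthless
hopeless
can't cope anymore
nobody would miss me
no one would care
everyone would be better off
thinking about suicide
suicidal thoughts
planning to end it
want to give up
slit my wrists
jump off a bridge
take all the pills
never want to wake up
want to sleep and not wake up
i give up
so tired
feel like
my life
bad day
tonight
alone
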