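# Terms removed from the ranked list by curation: frequent in distressed
# text but not specifically suicide-related (kept out of the final lexicon).
i give up
so tired
feel like
my life
bad day
tonight
alone
hopeless
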