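# English place names with US equivalents, excluded from profile-location
# matching (one per line, lowercase).
lincoln
boston
york
durham
lancaster
worcester
manchester
birmingham
cambridge
oxford
norfolk
suffolk
essex
bristol
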