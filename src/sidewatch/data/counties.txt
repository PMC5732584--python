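# English ceremonial counties (lowercase, one per line).
bedfordshire
berkshire
bristol
buckinghamshire
cambridgeshire
cheshire
cornwall
cumbria
derbyshire
devon
dorset
durham
east sussex
essex
gloucestershire
greater london
greater manchester
hampshire
herefordshire
hertfordshire
isle of wight
kent
lancashire
leicestershire
lincolnshire
merseyside
norfolk
north yorkshire
northamptonshire
northumberland
nottinghamshire
oxfordshire
rutland
shropshire
somerset
south yorkshire
staffordshire
suffolk
surrey
tyne and wear
warwickshire
west midlands
west sussex
west yorkshire
wiltshire
worcestershire
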