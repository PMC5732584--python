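%
1	joy
2	anger
3	grief
4	sadness
5	enthusiasm
6	surprise
7	love
8	hate
9	happiness
10	alarm
11	misery
12	levity
13	cheerfulness
14	trepidation
15	admiration
16	security
17	self_pity
18	belligerence
%
joy*	1
delight*	1	9
cheer*	13	9
jolly	12	13
jollity	12	13
gaiety	12	13
levity	12
playful*	12
silly	12
lol	12
haha*	12
funny	12
angry	2
anger*	2
rage*	2	18
furious	2
aggress*	18
belliger*	18
hostil*	18
grief	3	4
griev*	3	4
mourn*	3	4
loss	3	4
condolence*	3
sad	4
sadness	4
sorrow*	4	3
unhappy	4
miserable	11	4
misery	11	4
despair*	11	4
anguish	11	4
excite*	5
eager*	5
enthusias*	5
thrill*	5	6
surprise*	6
astonish*	6
shock*	6	10
wow	6
love*	7
adore*	7	15
affection*	7
darling	7
hate*	8
hatred	8
loathe*	8
despise*	8
happy	9
happier	9
happiest	9
happiness	9
glad	9
smile*	9	13
alarm*	10
panic*	10	14
dread*	14
trepidation	14
fear*	14
afraid	14
worried	14
admire*	15
admiration	15
respect*	15
proud	15
safe	16
secure	16
security	16
protect*	16
calm	16
selfpity	17
pity	17
victim	17
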