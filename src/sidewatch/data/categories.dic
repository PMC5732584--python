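%
1	death
2	health
3	money
4	religion
5	occupation
6	achievement
7	senses
8	cogmech
9	affect
10	social
11	family
12	friends
13	humans
14	anxiety
15	anger
16	sadness
17	posemo
18	negemo
19	certainty
20	inhibition
21	insight
22	causal
23	inclusive
24	exclusive
%
die*	1
dead	1
death*	1
suicid*	1
kill*	1
grave	1
funeral	1
coffin	1
bury	1
buried	1
overdose	1
sick*	2
ill	2
illness	2
doctor*	2
hospital*	2
medicine	2
therap*	2
clinic*	2
nurse*	2
money	3
cash	3
pay*	3	5
debt*	3
poor	3	18
rich	3
afford	3
cost*	3
god	4
pray*	4
church	4
faith	4
heaven	4
hell	4	18
bless*	4	17
holy	4
job*	5
work*	5
boss	5
office	5
career*	5
employ*	5
school*	5
colleg*	5
win*	6	17
won	6	17
achiev*	6	17
succe*	6	17
fail*	6	18	16
lose	6	18
lost	6	18
goal*	6
hear*	7
see	7
seeing	7
saw	7
feel*	7	9
touch*	7
taste*	7
smell*	7
listen*	7
think*	8	21
know*	8	21
becaus*	8	22
make*	8	22
reason*	8	21	22
should	8	20
ought	8	20
maybe	8
happ*	9	17
cried	9	16	18
cry*	9	16	18
love*	9	17
hate*	9	15	18
hurt*	9	18
mad	9	15	18
talk*	10
share*	10
friend*	10	12
parent*	10	11
famil*	10	11
mum	10	11
mother*	10	11
dad	10	11
father*	10	11
brother*	10	11
sister*	10	11
mate*	10	12
buddy	10	12
pal	10	12
people	10	13
person*	10	13
human*	13
man	13
woman	13
child*	13	11
boy*	13
girl*	13
guy*	13
worr*	14	18
anxi*	14	18
nervous*	14	18
afraid	14	18
fear*	14	18
panic*	14	18
scare*	14	18
tense	14	18
angry	15	18
anger*	15	18
rage*	15	18
annoy*	15	18
furious	15	18
kick*	15
fight*	15	18
sad	16	18
sadness	16	18
grief	16	18
griev*	16	18
miser*	16	18
lonel*	16	18
alone	16	18
depress*	16	18
hopeless*	16	18
sorrow*	16	18
tear*	16	18
happy	17	9
happier	17	9
joy*	17	9
great	17
good	17
nice	17
sweet	17
glad	17
hope	17
hoping	17
awful	18	9
terrible	18	9
horrible	18	9
worthless	18	16
useless	18
wrong	18
bad	18
worse	18
worst	18
always	19
never	19
certain*	19
definitely	19
sure	19
every	19
all	19
block*	20
constrain*	20
restrain*	20
stop*	20
quit*	20
insight*	21
understand*	21
realize*	21
realis*	21
aware*	21
why	22
cause*	22
effect*	22
hence	22
therefore	22
with	23
and	23
include*	23
both	23
together	23
but	24
without	24
except	24
exclude*	24
either	24
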