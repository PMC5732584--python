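%
1	home
2	religion
3	psychology
4	sociology
5	school
6	sport
7	medicine
8	music
9	weather
10	racing
11	transport
12	mathematics
13	agriculture
14	tv
15	law
%
house*	1
home	1
kitchen	1
garden	1
bedroom	1
roof	1
door	1
god	2
church*	2
pray*	2
faith	2
bible	2
priest*	2
mind	3
memory	3
emotion*	3
anxiety	3
depress*	3
mood*	3
therapy	3
society	4
social	4
community	4
culture	4
class	4
school*	5
teacher*	5
exam*	5
homework	5
student*	5
lesson*	5
football	6
match	6
team	6
goal	6
training	6
stadium	6
doctor*	7
hospital*	7
surgery	7
medicine	7
diagnos*	7
pill*	7
song*	8
music*	8
band	8
guitar	8
concert	8
album	8
rain*	9
sunny	9
weather	9
storm*	9
cloud*	9
snow*	9
race*	10
racing	10
run	10
running	10
driver*	10
lap	10
train	11
bus	11
car	11
road	11
station	11
flight	11
add	12
count*	12
number*	12
sum	12
equation*	12
grow*	13
farm*	13
harvest	13
crop*	13
field*	13
tv	14
television	14
series	14
episode*	14
channel	14
actor*	14
police	15
court	15
judge	15
lawyer*	15
crime*	15
officer*	15
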