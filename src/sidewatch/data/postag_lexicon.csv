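word,tag
i,PRP
you,PRP
he,PRP
she,PRP
it,PRP
we,PRP
they,PRP
me,PRP
him,PRP
her,PRP
us,PRP
them,PRP
myself,PRP
yourself,PRP
himself,PRP
herself,PRP
ourselves,PRP
themselves,PRP
my,PRP$
your,PRP$
his,PRP$
its,PRP$
our,PRP$
their,PRP$
the,DT
a,DT
an,DT
this,DT
that,DT
these,DT
those,DT
some,DT
any,DT
no,DT
every,DT
each,DT
and,CC
or,CC
but,CC
nor,CC
yet,CC
so,CC
in,IN
on,IN
at,IN
of,IN
for,IN
with,IN
by,IN
from,IN
about,IN
into,IN
over,IN
under,IN
after,IN
before,IN
because,IN
if,IN
while,IN
since,IN
than,IN
to,TO
is,VBZ
am,VBP
are,VBP
was,VBD
were,VBD
be,VB
been,VBN
being,VBG
do,VBP
does,VBZ
did,VBD
have,VBP
has,VBZ
had,VBD
go,VB
goes,VBZ
went,VBD
gone,VBN
get,VB
got,VBD
make,VB
made,VBD
take,VB
took,VBD
taken,VBN
know,VBP
knew,VBD
think,VBP
thought,VBD
feel,VBP
felt,VBD
want,VBP
wanted,VBD
need,VBP
say,VBP
said,VBD
see,VBP
saw,VBD
seen,VBN
come,VB
came,VBD
will,MD
would,MD
can,MD
could,MD
shall,MD
should,MD
may,MD
might,MD
must,MD
cannot,MD
can't,MD
won't,MD
don't,VBP
doesn't,VBZ
didn't,VBD
couldn't,MD
wouldn't,MD
shouldn't,MD
isn't,VBZ
wasn't,VBD
not,RB
never,RB
always,RB
really,RB
very,RB
too,RB
just,RB
now,RB
here,RB
there,EX
again,RB
still,RB
already,RB
soon,RB
anymore,RB
today,NN
tomorrow,NN
tonight,NN
yesterday,NN
good,JJ
bad,JJ
sad,JJ
happy,JJ
new,JJ
old,JJ
big,JJ
small,JJ
nice,JJ
great,JJ
tired,JJ
alone,JJ
dead,JJ
suicidal,JJ
better,JJR
worse,JJR
best,JJS
worst,JJS
such,PDT
rather,RB
quite,PDT
what,WP
who,WP
whom,WP
whose,WP$
which,WDT
when,WRB
where,WRB
why,WRB
how,WRB
oh,UH
wow,UH
hey,UH
please,UH
ok,UH
okay,UH
yes,UH
yeah,UH
life,NN
time,NN
day,NN
night,NN
people,NNS
man,NN
woman,NN
world,NN
thing,NN
things,NNS
one,CD
two,CD
three,CD
four,CD
five,CD
ten,CD
hundred,CD
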