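token,positive,negative
good,0.75,0.0
great,0.75,0.0
nice,0.625,0.0
happy,0.875,0.0
happier,0.75,0.0
glad,0.625,0.0
love,0.625,0.0
loved,0.625,0.0
lovely,0.75,0.0
wonderful,0.75,0.0
amazing,0.75,0.0
awesome,0.75,0.0
best,0.75,0.0
better,0.5,0.0
beautiful,0.75,0.0
fun,0.625,0.0
funny,0.5,0.125
joy,0.875,0.0
hope,0.625,0.0
hopeful,0.625,0.0
sweet,0.625,0.0
smile,0.625,0.0
proud,0.625,0.0
calm,0.5,0.0
safe,0.5,0.0
win,0.625,0.0
won,0.5,0.0
support,0.5,0.0
help,0.375,0.0
care,0.375,0.0
thanks,0.5,0.0
thank,0.5,0.0
friend,0.375,0.0
bad,0.0,0.625
worse,0.0,0.625
worst,0.0,0.75
sad,0.0,0.75
sadness,0.0,0.75
unhappy,0.0,0.625
miserable,0.0,0.75
misery,0.0,0.75
awful,0.0,0.75
terrible,0.0,0.75
horrible,0.0,0.75
hate,0.0,0.75
hated,0.0,0.625
hurt,0.0,0.625
hurts,0.0,0.625
pain,0.0,0.625
painful,0.0,0.625
cry,0.0,0.625
crying,0.0,0.625
cried,0.0,0.5
tears,0.0,0.5
alone,0.0,0.375
lonely,0.0,0.625
worthless,0.0,0.75
useless,0.0,0.625
hopeless,0.0,0.75
depressed,0.0,0.75
depressing,0.0,0.625
anxious,0.0,0.625
anxiety,0.0,0.625
afraid,0.0,0.625
fear,0.0,0.625
scared,0.0,0.625
panic,0.0,0.625
angry,0.0,0.625
anger,0.0,0.625
rage,0.0,0.625
annoyed,0.0,0.5
tired,0.0,0.375
exhausted,0.0,0.5
sick,0.0,0.5
ill,0.0,0.5
die,0.0,0.625
died,0.0,0.5
dead,0.0,0.625
death,0.0,0.625
kill,0.0,0.625
killed,0.0,0.625
suicide,0.0,0.75
suicidal,0.0,0.75
fail,0.0,0.625
failed,0.0,0.625
failure,0.0,0.625
lost,0.0,0.5
loss,0.0,0.5
wrong,0.0,0.5
broken,0.0,0.5
grief,0.0,0.625
sorrow,0.0,0.625
sorry,0.0,0.375
miss,0.0,0.375
missing,0.0,0.375
dark,0.0,0.25
empty,0.0,0.375
numb,0.0,0.5
shame,0.0,0.625
ashamed,0.0,0.625
guilty,0.0,0.625
stress,0.0,0.5
stressed,0.0,0.5
trapped,0.0,0.5
stuck,0.0,0.375
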