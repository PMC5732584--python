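id,class_hint,pattern,description
c1_r1,c1,"(cutting|depres\w*|suicid\w*|these|bad|sad)\s+(\w+\s+)?(thought|feel)\w*","suicidal/cutting/depressive/bad/sad/these ... thoughts/feelings"
c1_r2,c1,"wan\w*\s+(to\s+)?d(ie|ying)\b","want/wanted/wanting/wanna (to) die"
c1_r3,c1,"end\w*\s+(it\s+all|my\s+life|it)\b","end/ending it all, end my life, end it"
c1_r4,c1,"(can'?t|don'?t|couldn'?t|won'?t)\s+(want\s+to\s+)?(take\s+(it\s+)?any\s?mo\w*|go\s+on|live\b|cope\w*|be\s+alive|stay\s+alive|exist)","can't take (it) anymore, can't go on, don't want to live/cope/be alive/exist"
c1_r5,c1,"(never|not)\s+(want\s+to\s+)?wake(\s?up)?\b","asleep and never wake (up), not want to wake up"
c1_w_trigger_warning,c1,"\btrigger\s+warning\b",word-list: trigger warning
c1_w_tw,c1,"\btw\b",word-list: tw
c1_w_eating_disorder,c1,"\beating\s+disorder\b",word-list: eating disorder
c1_w_death,c1,"\bdeath\b",word-list: death
c1_w_selfharm,c1,"\bself\s?harm\b",word-list: selfharm / self harm
c1_w_anxiety,c1,"\banxiety\b",word-list: anxiety
c1_w_pain,c1,"\bpain\b",word-list: pain
c2_r1,c2,"(need\w*|ask\w*|call\w*|offer\w*)\s+(\w+\s+)?help","call/offer/ask for/of help"
c2_w_shut,c2,"\bshut\b",word-list: shut (e.g. website shut down)
c2_w_stop,c2,"\bstop\b",word-list: stop (e.g. stop the bullying)
c3_r1,c3,"(kill\w*|hat(e|es|ed|ing)|throw\w*)\s+(myself|me\b)","kill/killing/hate/throw ... myself/me"
c3_r2,c3,"\bf[\W_]{1,2}k\b|\bfuck\w*","masked or plain swearwords"
c3_r3,c3,"(boy|girl)\s?friend","boyfriend / girlfriend"
c3_r4,c3,"\bjust\b.+\blike\b","flippant 'just ... like' constructions"
c3_w_work,c3,"\bwork\b",word-list: work (flippant context)
c3_w_school,c3,"\bschool\b",word-list: school (flippant context)
c4_r1,c4,"(talk\w*|speak\w*)\s+to\s+(some\s?(one|body)|any\s?(one|body)|no\s?(one|body)|one\b)","talk/speak to someone/somebody/anyone"
c4_w_web,c4,"\bweb\b",word-list: web
c4_w_blog,c4,"\bblog\w*",word-list: blog
c4_w_health,c4,"\bhealth\b",word-list: health
c4_w_advice,c4,"\badvice\b",word-list: advice
c5_r1,c5,"\bmiss\w*\s+(you|her|him)\b","miss/missing you/her/him"
c5_r2,c5,"(kill\w*|die[ds]?\b|dying|comm\w*)\W+(\w+\W+){0,4}(day|month|year)s?\b","killed/died/committed ... day/month/year time references"
c5_w_rip,c5,"\brip\b",word-list: rip
c6_r1,c6,"(took|take\w*)\s+(\w+\s+)?own\s+life","took/taken his/her own life"
c6_w_hanged,c6,"\bhang(ed|ing)\b",word-list: hanged / hanging
c6_w_overdose,c6,"\boverdose\b",word-list: overdose
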