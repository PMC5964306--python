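%
1	posemo
2	negemo
%
happ*	1
joy*	1
love*	1
lovin*	1
glad	1
great	1
good	1
nice	1
fun	1
funn*	1
amaz*	1
awesome	1
excit*	1
wonderful	1
fantastic	1
brilliant	1
delight*	1
cheer*	1
smile	1
smiling	1
laugh*	1
proud	1
hope	1
hopeful	1
grateful	1
thankful	1
blessed	1
sweet	1
beautiful	1
win	1
winning	1
yay	1
woo	1
woohoo	1
lol	1
haha	1
xoxo	1
:)	1
:-)	1
;)	1
=)	1
sad	2
sadde*	2
unhappy	2
miserable	2
depress*	2
cry	2
crying	2
cried	2
tear*	2
hurt*	2
pain*	2
awful	2
terrible	2
horrible	2
hate*	2
hating	2
angry	2
anger	2
annoy*	2
upset	2
worr*	2
anxious	2
anxiety	2
afraid	2
fear*	2
lonel*	2
alone	2
gloom*	2
grief	2
griev*	2
broken	2
lost	2
tired	2
exhaust*	2
stress*	2
fail*	2
ugh	2
fml	2
:(	2
:-(	2
:'(	2
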