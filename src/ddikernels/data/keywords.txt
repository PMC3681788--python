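abolish
accelerate
accumulate
activate
affect
aggravate
alter
amplify
antagonize
attenuate
augment
block
boost
cause
change
coadminister
counteract
decline
decrease
delay
depress
desensitize
diminish
displace
disrupt
double
elevate
enhance
exacerbate
halve
impair
inactivate
increase
induce
inhibit
intensify
interact
interfere
lower
metabolize
modify
modulate
oppose
potentiate
precipitate
prevent
produce
prolong
promote
raise
reduce
sensitize
slow
stimulate
strengthen
suppress
synergize
weaken
worsen
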