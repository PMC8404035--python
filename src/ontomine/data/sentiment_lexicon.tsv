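abysmal	-0.9
afraid	-0.7
agony	-0.9
angry	-0.7
anxious	-0.6
awful	-0.8
bad	-0.5
bleak	-0.6
crying	-0.7
depressed	-0.8
desperate	-0.7
devastated	-0.9
difficult	-0.4
disappointed	-0.6
distressed	-0.7
dreadful	-0.8
exhausted	-0.5
fear	-0.6
frightened	-0.7
frustrating	-0.6
grim	-0.6
heartbroken	-0.9
helpless	-0.7
hopeless	-0.8
horrible	-0.8
hurt	-0.5
lonely	-0.6
miserable	-0.8
nervous	-0.5
overwhelmed	-0.5
panic	-0.7
sad	-0.6
scared	-0.7
severe	-0.4
sore	-0.4
struggling	-0.5
suffering	-0.7
terrible	-0.8
terrified	-0.9
unbearable	-0.9
upset	-0.6
worried	-0.6
worse	-0.5
worst	-0.8
fine	0.3
okay	0.2
stable	0.3
steady	0.2
amazing	0.9
better	0.4
brilliant	0.8
calm	0.4
cheerful	0.7
comfort	0.5
confident	0.6
delighted	0.8
encouraging	0.6
excellent	0.9
fantastic	0.9
glad	0.6
good	0.5
grateful	0.7
happy	0.7
healed	0.7
healthy	0.6
hope	0.4
hopeful	0.6
improved	0.5
improving	0.5
joy	0.8
lovely	0.7
lucky	0.5
optimistic	0.6
perfect	0.9
pleased	0.6
positive	0.5
reassured	0.6
relief	0.6
relieved	0.6
smiling	0.6
splendid	0.8
strong	0.4
succeeded	0.7
super	0.7
supportive	0.6
wonderful	0.9
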