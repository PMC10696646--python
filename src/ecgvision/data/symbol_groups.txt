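# Raw WFDB annotation symbol -> grouped classification symbol.
# 14 beat classes pass through unchanged; beat symbols outside the class
# vocabulary collapse to Q (unclassifiable beat); every non-beat symbol
# collapses to Z. Symbols not listed here are treated as non-beat (Z).
# Format: <raw> <grouped>, whitespace separated, one pair per line.
N N
L L
R R
V V
A A
f f
F F
j j
a a
E E
J J
Q Q
e e
S S
B Q
/ Q
n Q
r Q
? Q
! Z
[ Z
] Z
x Z
( Z
) Z
p Z
t Z
u Z
^ Z
| Z
~ Z
+ Z
s Z
T Z
* Z
D Z
= Z
" Z
@ Z
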