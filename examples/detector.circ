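#input x
#output y
#init 00
q2' = q1 & x & !q2 | q2 & !q1
q1' = q1 & q2 & x | q2 & !q1 & !x | x & !q1 & !q2
y = q1 & q2 & x
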