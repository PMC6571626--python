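#input x1
#output y1
#init 00
q1' = !q1 & !q2 | !q2 & !x1
q2' = q1 & !q2 | q1 & x1
y1 = !q1 & !q2
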