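#input: T
#output: F H O
F , d , F
H , d , F
O , d , H
T , d , O
#context[0]: T
#context[1]: 
#context[2]: 
#context[3]: 
#context[4]: 
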