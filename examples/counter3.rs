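#input: e0
#output: e1 e2 e3
e0 , e1 , e1
e0 e1 , e2 , e2
e0 e1 e2 , e3 , e3
e1 , e0 , e1
e2 , e0 , e2
e2 , e1 , e2
e3 , e0 , e3
e3 , e1 , e3
e3 , e2 , e3
#context[0]: e0
#context[1]: e0
#context[2]: e0
#context[3]: e0
#context[4]: e0
#context[5]: e0
#context[6]: e0
#context[7]: e0
#context[8]: e0
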