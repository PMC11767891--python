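# L-glutamate: C1/C5 carboxyl carbons unprotonated
metabolite: glutamate
carbons: 5
carbon: 1 - 177.2
carbon: 2 3.75 57.3
carbon: 3 2.08 29.7
carbon: 4 2.34 36.2
carbon: 5 - 183.8
jcc: 1 2 53.4
jcc: 2 3 34.8
jcc: 3 4 34.1
jcc: 4 5 51.4
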