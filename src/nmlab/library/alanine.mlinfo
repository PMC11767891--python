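# L-alanine
metabolite: alanine
carbons: 3
carbon: 1 - 178.5
carbon: 2 3.78 53.2
carbon: 3 1.48 18.9
jcc: 1 2 54.0
jcc: 2 3 35.1
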