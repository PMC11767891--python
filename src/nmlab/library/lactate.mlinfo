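# L-lactate: 3 carbons, carboxyl C1 carries no proton and is invisible in HSQC
metabolite: lactate
carbons: 3
carbon: 1 - 183.3
carbon: 2 4.10 71.3
carbon: 3 1.31 22.7
jcc: 1 2 54.2
jcc: 2 3 37.1
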