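>EBOXSYN01 Ebox-bHLH-synthetic
A [ 15 15 3 91 3 3 3 3 15 15 ]
C [ 20 15 91 3 91 3 3 3 55 50 ]
G [ 50 55 3 3 3 91 3 91 15 20 ]
T [ 15 15 3 3 3 3 91 3 15 15 ]
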