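origin 4 12
geo 54.0 0.0 50.0
0 0 1 1 1 1 1 1 1 1 1 1 1 1
0 1 1 1 1 1 1 1 1 1 1 1 1 1
1 1 1 1 0 0 1 1 1 1 1 1 1 1
1 1 1 0 0 0 1 1 1 1 1 1 1 1
1 1 1 1 0 0 1 1 1 1 1 1 1 1
0 1 1 1 1 1 1 1 1 1 1 1 1 1
0 0 1 1 1 1 1 1 0 1 1 1 1 1
0 0 0 1 1 1 1 0 0 1 1 1 1 1
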