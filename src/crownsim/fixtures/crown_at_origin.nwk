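((A|A:6,B|X:3)L:4,(C|A:5,D|A:5)R:5);
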