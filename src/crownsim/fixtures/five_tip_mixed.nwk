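((A|A:8,(B|A:5,C|A:5)M:3)L:4,(D|X:4,F|X:2)R:6);
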