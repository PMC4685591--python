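(A|X:4,((B|A:3,C|A:3)n2:3,D|X:2)n1:4);
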