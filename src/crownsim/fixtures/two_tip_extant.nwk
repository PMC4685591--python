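(L1|A:10,L2|A:10);
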