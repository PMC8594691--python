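sample
S1
S2
S3
S4
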