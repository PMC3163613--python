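answer,count
yes,74
no,244
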