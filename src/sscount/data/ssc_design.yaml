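# 4+1 Single Sample Count design with equal 0.5 innocuous probabilities
model: ssc
m: 4
probs: equal
alpha: 0.05
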