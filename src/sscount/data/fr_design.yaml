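# Two-dice Forced Response device: 2-4 forces 'yes', 11-12 forces 'no',
# 5-10 requires an honest answer.
model: fr
pi_forced_yes: 1/6
pi_forced_no: 1/12
pi_honest: 3/4
alpha: 0.05
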