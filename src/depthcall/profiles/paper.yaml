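# full-fidelity training profile
learning_rate: 0.0003
batch_size: 5000
epochs: 30
flank: 16
min_af: 0.2
min_depth: 4
lambda1: 1.0
lambda2: 1.0
lambda3: 0.1
gamma: 2.0
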