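name: ramp_hold_release_fixed
parameters: {}
seed: 1
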