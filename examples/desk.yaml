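# full desk-scale preset: 400 cases at 64 px, tiny backbones
seed: 42
scale: desk
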