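# Heat-shock pulse experiment: fit the reporter mRNA half-life
preset: heatshock
seed: 1
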