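cellular process
biological phase
reproductive process
multi-organism process
localization
interspecies interaction between organisms
reproduction
biological regulation
response to stimulus
signaling
developmental process
rhythmic process
multicellular organismal process
metabolic process
growth
immune system process
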