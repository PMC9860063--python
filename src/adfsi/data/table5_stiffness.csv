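model,E_MPa,CA,SMA
3rd order Ogden,0.732,91,93
Neo-Hookean,0.732,95,96
Neo-Hookean,0.1,67,71
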