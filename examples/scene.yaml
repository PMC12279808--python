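image_size: 320
n_plants: 3
whorl_radius: [10, 16]
leaves_per_plant: 7
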