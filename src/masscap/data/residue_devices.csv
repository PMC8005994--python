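device,extraction_volume_ml,n_swabs,total_volume_ml
weighing_boat,5,0,5
spatula,5,0,5
pestle,10,2,12
powder_spreader,10,2,12
mixing_bowl,15,3,18
capsule_filling_machine,19,6,25
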