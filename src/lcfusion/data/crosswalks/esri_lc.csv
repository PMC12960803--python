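source_code,source_label,target_code,target_label
1,Water,7,Water
2,Trees,3,Forest
3,Grass,5,Grass
4,Flooded Vegetation,8,Wet
5,Crops,2,Crop
6,Scrub/Shrub,4,Shrub
7,Built Area,1,Built
8,Bare Ground,6,Bare
9,Snow/Ice,9,Snow
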