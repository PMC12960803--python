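source_code,source_label,target_code,target_label
0,Water,7,Water
1,Trees,3,Forest
2,Grass,5,Grass
3,Flooded Vegetation,8,Wet
4,Crops,2,Crop
5,Scrub/Shrub,4,Shrub
6,Built Area,1,Built
7,Bare Ground,6,Bare
8,Snow/Ice,9,Snow
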