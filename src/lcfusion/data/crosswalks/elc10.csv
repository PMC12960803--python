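source_code,source_label,target_code,target_label
1,Artificial land,1,Built
2,Cropland,2,Crop
3,Woodland,3,Forest
4,Shrubland,4,Shrub
5,Grassland,5,Grass
6,Bareland,6,Bare
7,Water,7,Water
8,Wetlands,8,Wet
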