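source_code,source_label,target_code,target_label
10,Tree cover,3,Forest
20,Shrubland,4,Shrub
30,Grassland,5,Grass
40,Cropland,2,Crop
50,Built-up,1,Built
60,Bare / sparse vegetation,6,Bare
70,Snow and Ice,9,Snow
80,Permanent water bodies,7,Water
90,Herbaceous wetland,8,Wet
100,Moss and lichen,6,Bare
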