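source_code,source_label,target_code,target_label
62,Artificial surfaces,1,Built
73,Cultivated areas,2,Crop
81,Broadleaf tree cover,3,Forest
82,Coniferous tree cover,3,Forest
102,Herbaceous vegetation,5,Grass
103,Moors and heathland,4,Shrub
105,Marshes,8,Wet
106,Peatbogs,8,Wet
121,Natural material surfaces,6,Bare
123,Permanent snow cover,9,Snow
162,Water bodies,7,Water
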