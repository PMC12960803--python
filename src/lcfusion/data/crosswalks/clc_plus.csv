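source_code,source_label,target_code,target_label
1,Sealed,1,Built
2,Woody needle leaved trees,3,Forest
3,Woody broadleaved deciduous trees,3,Forest
4,Woody broadleaved evergreen trees,3,Forest
5,Low-growing woody plants,4,Shrub
6,Permanent herbaceous,5,Grass
7,Periodically herbaceous,2,Crop
8,Lichens and mosses,6,Bare
9,Non and sparsely-vegetated,6,Bare
10,Water,7,Water
11,Snow and ice,9,Snow
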