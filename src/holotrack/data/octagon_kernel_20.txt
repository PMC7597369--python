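# 20x20 raster of a regular octagon (diameter 168 nm at 8.4 nm/px):
# a 20 px square with 6 px 45-degree corner cuts. Fixed bit-exactly.
00000011111111000000
00000111111111100000
00001111111111110000
00011111111111111000
00111111111111111100
01111111111111111110
11111111111111111111
11111111111111111111
11111111111111111111
11111111111111111111
11111111111111111111
11111111111111111111
11111111111111111111
11111111111111111111
01111111111111111110
00111111111111111100
00011111111111111000
00001111111111110000
00000111111111100000
00000011111111000000
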