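# 53-channel fNIRS montage: channel -> cortical region [hemisphere]
# Regions: SMA (bilateral supplementary motor area), M1 (primary motor cortex),
# S1 (primary somatosensory cortex), Wernicke (posterior language cortex),
# SAC (somatosensory association cortex). Channel 28 sits at Cz (10-20 system).
# The left/right assignment is SYNTHETIC (a fixed, arbitrary split of each
# region's channel list): the true per-channel laterality of this montage is
# not published. It exists so hemispheric network nodes can be formed for
# simulation and connectivity analysis; replace with a measured map if known.
# Format: <channel> <region> [hemisphere]
1 Wernicke left
2 S1 left
3 Wernicke left
4 Wernicke left
5 Wernicke left
6 Wernicke left
7 SMA left
8 M1 left
9 SMA left
10 Wernicke left
11 Wernicke left
12 SAC left
13 M1 left
14 M1 left
15 SMA left
16 SMA left
17 M1 left
18 S1 left
19 SMA left
20 M1 left
21 SMA left
22 SMA left
23 SMA left
24 SAC left
25 M1 right
26 SAC right
27 SMA left
28 SMA left
29 SMA right
30 SMA right
31 M1 right
32 S1 right
33 SMA right
34 M1 right
35 SMA right
36 SMA right
37 SMA right
38 SAC right
39 Wernicke right
40 Wernicke right
41 SMA right
42 M1 right
43 SMA right
44 M1 right
45 Wernicke right
46 Wernicke right
47 Wernicke right
48 SMA right
49 M1 right
50 SMA right
51 Wernicke right
52 Wernicke right
53 S1 right
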