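genome_id	query_ID	query_length	identity%
Amphidinium carterae	AT1G14710.1_ALKBH10B	2429 bp	44.2
Amphidinium carterae	AT1G14710.2_ALKBH10B	2513 bp	45.8
Amphidinium carterae	AT1G48980.1_ALKBH9B	1830 bp	48.2
Amphidinium carterae	AT1G48980.2_ALKBH9B	1818 bp	46.6
Amphidinium carterae	AT1G48980.3_ALKBH9B	1832 bp	48.2
Amphidinium carterae	AT1G48980.4_ALKBH9B	1745 bp	48.2
Amphidinium carterae	AT2G17970.1_ALKBH9B	1797 bp	45.1
Amphidinium carterae	AT2G17970.2_ALKBH9B	1981 bp	45.7
Amphidinium carterae	AT2G17970.3_ALKBH9B	2119 bp	45.4
Amphidinium carterae	AT2G48080.1_ALKBH10B	1519 bp	46.7
Amphidinium carterae	AT3G05680.1_VIRILIZER	6833 bp	100
Amphidinium carterae	AT3G05680.2_VIRILIZER	6904 bp	100
Amphidinium carterae	AT3G54170.1_FIP37	1262 bp	45.7
Amphidinium carterae	AT4G02940.1_ALKBH10B	2112 bp	44.4
Amphidinium carterae	AT4G09980.1_MTB	3393 bp	43.4
Amphidinium carterae	AT4G09980.2_MTB	3342 bp	46.5
Amphidinium carterae	AT4G10760.1_MTA	2227 bp	46.9
Amphidinium carterae	AT4G36090.1_ALKBH9B	1830 bp	44.8
Amphidinium carterae	AT4G36090.2_ALKBH9B	2025 bp	100
Amphidinium carterae	AT4G36090.3_ALKBH9B	1707 bp	45.7
Amphidinium carterae	AT5G01160.1_HAKAI	1404 bp	46
Amphidinium carterae	NP_001042682.1_MTB XM_015763885.2	4254 bp	40.5
Amphidinium carterae	NP_001047707.1_MTA XM_015769953.1	2476 bp	45.4
Amphidinium carterae	NP_001048963.2_MTB XM_015776811.2	2832 bp	42.9
Amphidinium carterae	NP_001049502.1_ALKBH10B XM_015775307.2	2532 bp	100
Amphidinium carterae	NP_001056738.1_ALKBH9B XM_015787389.2	2221 bp	46.3
Amphidinium carterae	NP_001057630.2_FIP37 XM_015788828.2	1428 bp	42.6
Amphidinium carterae	NP_001064055.1_ALKBH10B XM_015759337.2	2380 bp	42.5
Amphidinium carterae	NP_001064723.2_MTB XM_015759054.2	3607 bp	100
Amphidinium carterae	NP_001064945.2_HAKAI XM_015758095.2	1685 bp	43.3
Cylindrotheca fusiformis	AT1G14710.1_ALKBH10B	2429 bp	49.8
Cylindrotheca fusiformis	AT1G14710.2_ALKBH10B	2513 bp	46.3
Cylindrotheca fusiformis	AT1G48980.1_ALKBH9B	1830 bp	42
Cylindrotheca fusiformis	AT1G48980.2_ALKBH9B	1818 bp	42.4
Cylindrotheca fusiformis	AT1G48980.3_ALKBH9B	1832 bp	42
Cylindrotheca fusiformis	AT1G48980.4_ALKBH9B	1745 bp	44.9
Cylindrotheca fusiformis	AT2G17970.1_ALKBH9B	1797 bp	49.7
Cylindrotheca fusiformis	AT2G17970.2_ALKBH9B	1981 bp	45.1
Cylindrotheca fusiformis	AT2G17970.3_ALKBH9B	2119 bp	47.6
Cylindrotheca fusiformis	AT2G48080.1_ALKBH10B	1519 bp	42.1
Cylindrotheca fusiformis	AT3G05680.1_VIRILIZER	6833 bp	100
Cylindrotheca fusiformis	AT3G05680.2_VIRILIZER	6904 bp	100
Cylindrotheca fusiformis	AT3G54170.1_FIP37	1262 bp	44.6
Cylindrotheca fusiformis	AT4G02940.1_ALKBH10B	2112 bp	42
Cylindrotheca fusiformis	AT4G09980.1_MTB	3393 bp	100
Cylindrotheca fusiformis	AT4G09980.2_MTB	3342 bp	100
Cylindrotheca fusiformis	AT4G10760.1_MTA	2227 bp	84.6
Cylindrotheca fusiformis	AT4G36090.1_ALKBH9B	1830 bp	46.7
Cylindrotheca fusiformis	AT4G36090.2_ALKBH9B	2025 bp	46.9
Cylindrotheca fusiformis	AT4G36090.3_ALKBH9B	1707 bp	46.6
Cylindrotheca fusiformis	AT5G01160.1_HAKAI	1404 bp	43.1
Cylindrotheca fusiformis	NP_001047707.1_MTA XM_015769953.1	2476 bp	45.6
Cylindrotheca fusiformis	NP_001049502.1_ALKBH10B XM_015775307.2	2532 bp	40.6
Cylindrotheca fusiformis	NP_001056738.1_ALKBH9B XM_015787389.2	2221 bp	53
Cylindrotheca fusiformis	NP_001057630.2_FIP37 XM_015788828.2	1428 bp	40.5
Cylindrotheca fusiformis	NP_001064055.1_ALKBH10B XM_015759337.2	2380 bp	47
Cylindrotheca fusiformis	NP_001064723.2_MTB XM_015759054.2	3607 bp	40.4
Cylindrotheca fusiformis	NP_001064945.2_HAKAI XM_015758095.2	1685 bp	42.5
Tetraselmis striata	AT1G14710.1_ALKBH10B	2429 bp	40.5
Tetraselmis striata	AT1G14710.2_ALKBH10B	2513 bp	40.5
Tetraselmis striata	AT1G48980.1_ALKBH9B	1830 bp	43.7
Tetraselmis striata	AT1G48980.3_ALKBH9B	1832 bp	43.7
Tetraselmis striata	AT1G48980.4_ALKBH9B	1745 bp	43.7
Tetraselmis striata	AT2G48080.1_ALKBH10B	1519 bp	44
Tetraselmis striata	AT3G05680.1_VIRILIZER	6833 bp	100
Tetraselmis striata	AT3G05680.2_VIRILIZER	6904 bp	100
Tetraselmis striata	AT3G54170.1_FIP37	1262 bp	42
Tetraselmis striata	AT4G10760.1_MTA	2227 bp	42.4
Tetraselmis striata	AT4G36090.1_ALKBH9B	1830 bp	46.7
Tetraselmis striata	AT4G36090.2_ALKBH9B	2025 bp	46.1
Tetraselmis striata	AT4G36090.3_ALKBH9B	1707 bp	46.1
Tetraselmis striata	AT5G01160.1_HAKAI	1404 bp	42.6
Tetraselmis striata	NP_001042682.1_MTB XM_015763885.2	4254 bp	100
Tetraselmis striata	NP_001047707.1_MTA XM_015769953.1	2476 bp	48.8
Tetraselmis striata	NP_001048963.2_MTB XM_015776811.2	2832 bp	40.9
Tetraselmis striata	NP_001056738.1_ALKBH9B XM_015787389.2	2221 bp	42.9
Tetraselmis striata	NP_001057630.2_FIP37 XM_015788828.2	1428 bp	45
Tetraselmis striata	NP_001064055.1_ALKBH10B XM_015759337.2	2380 bp	45.9
Tetraselmis striata	NP_001064945.2_HAKAI XM_015758095.2	1685 bp	48.3
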