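"""Frozen reference values for the full scenario sweep.

Each row: (area_label, mode, response_time_min, printed_radius_km,
printed_catchment_km2, catchment_decimals, units, {unit_cost: total_cost}).
Printed catchments are truncated to the stated decimals, so the computed
value must lie within one unit in the last printed digit.
"""

FULL_TABLE = [
    # --- full area, 3930 km² ---
    ("full_area", "stationary", 3, 0.10, 0.025, 3, 151_266,
     {170: 25_715_220, 263: 39_782_958, 405: 61_262_730}),
    ("full_area", "stationary", 4, 0.15, 0.058, 3, 67_230,
     {170: 11_429_100, 263: 17_681_490, 405: 27_228_150}),
    ("full_area", "stationary", 5, 0.20, 0.103, 3, 37_817,
     {170: 6_428_890, 263: 9_945_871, 405: 15_315_885}),
    ("full_area", "stationary", 6, 0.25, 0.162, 3, 24_203,
     {170: 4_114_510, 263: 6_365_389, 405: 9_802_215}),
    ("full_area", "stationary", 7, 0.30, 0.233, 3, 16_808,
     {170: 2_857_360, 263: 4_420_504, 405: 6_807_240}),
    ("full_area", "stationary", 8, 0.35, 0.318, 3, 12_349,
     {170: 2_099_330, 263: 3_247_787, 405: 5_001_345}),
    ("full_area", "airborne", 3, 2.0, 10.39, 2, 569,
     {32_248: 18_349_112, 45_000: 25_605_000, 55_000: 31_295_000}),
    ("full_area", "airborne", 4, 3.0, 23.38, 2, 254,
     {32_248: 8_190_992, 45_000: 11_430_000, 55_000: 13_970_000}),
    ("full_area", "airborne", 5, 4.0, 41.56, 2, 143,
     {32_248: 4_611_464, 45_000: 6_435_000, 55_000: 7_865_000}),
    ("full_area", "airborne", 6, 5.0, 64.95, 2, 92,
     {32_248: 2_966_816, 45_000: 4_140_000, 55_000: 5_060_000}),
    ("full_area", "airborne", 7, 6.0, 93.53, 2, 65,
     {32_248: 2_096_120, 45_000: 2_925_000, 55_000: 3_575_000}),
    ("full_area", "airborne", 8, 7.0, 127.30, 2, 47,
     {32_248: 1_515_656, 45_000: 2_115_000, 55_000: 2_585_000}),
    # --- hot spots, 680.4 km² ---
    ("hot_spots", "stationary", 3, 0.10, 0.025, 3, 26_189,
     {170: 4_452_130, 263: 6_887_707, 405: 10_606_545}),
    ("hot_spots", "stationary", 4, 0.15, 0.058, 3, 11_640,
     {170: 1_978_800, 263: 3_061_320, 405: 4_714_200}),
    ("hot_spots", "stationary", 5, 0.20, 0.103, 3, 6_548,
     {170: 1_113_160, 263: 1_722_124, 405: 2_651_940}),
    ("hot_spots", "stationary", 6, 0.25, 0.162, 3, 4_191,
     {170: 712_470, 263: 1_102_233, 405: 1_697_355}),
    ("hot_spots", "stationary", 7, 0.30, 0.233, 3, 2_910,
     {170: 494_700, 263: 765_330, 405: 1_178_550}),
    ("hot_spots", "stationary", 8, 0.35, 0.318, 3, 2_138,
     {170: 363_460, 263: 562_294, 405: 865_890}),
    ("hot_spots", "airborne", 3, 2.0, 10.39, 2, 99,
     {32_248: 3_192_552, 45_000: 4_455_000, 55_000: 5_445_000}),
    ("hot_spots", "airborne", 4, 3.0, 23.38, 2, 45,
     {32_248: 1_451_160, 45_000: 2_025_000, 55_000: 2_475_000}),
    ("hot_spots", "airborne", 5, 4.0, 41.56, 2, 26,
     {32_248: 838_448, 45_000: 1_170_000, 55_000: 1_430_000}),
    ("hot_spots", "airborne", 6, 5.0, 64.95, 2, 17,
     {32_248: 548_216, 45_000: 765_000, 55_000: 935_000}),
    ("hot_spots", "airborne", 7, 6.0, 93.53, 2, 12,
     {32_248: 386_976, 45_000: 540_000, 55_000: 660_000}),
    ("hot_spots", "airborne", 8, 7.0, 127.30, 2, 9,
     {32_248: 290_232, 45_000: 405_000, 55_000: 495_000}),
]

AREA_KM2 = {"full_area": 3930.0, "hot_spots": 680.4}
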