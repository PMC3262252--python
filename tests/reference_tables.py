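"""Published Arrhenius parameter tables used as consistency fixtures.

Each row gives an activation energy (kJ/mol) and the same rate parameter
printed at two temperatures; internal consistency means the value at the
second temperature follows from the value at the first through the Arrhenius
ratio law, to the four printed decimals.

``DAY_NIGHT_ROWS`` come from a day/night-split parameterization tabulated at
T_day = 290.15 K and T_night = 285.15 K whose printed rates *increase toward
the colder night* (the decreasing-with-temperature sign convention).
``TWO_TEMPERATURE_ROWS`` are tabulated at 285.15 K and 300.15 K under the
standard convention (rates increase with temperature).  Two rows of the
latter table are printed with their energies swapped relative to their own
rate values and are excluded here.
"""

T_DAY = 290.15
T_NIGHT = 285.15
T_LO = 285.15
T_HI = 300.15

# (label, E kJ/mol, k at T_day, k at T_night); decreasing-with-T convention
DAY_NIGHT_ROWS = [
    ("n6_unbalanced", 13.7721, 7.6670, 8.4742),
    ("m16_unbalanced", 39.1133, 11.0158, 14.6380),
    ("p6_unbalanced", 41.5837, 0.2471, 0.3343),
    ("m4_unbalanced", 13.7658, 3.6320, 4.0142),
    ("n6_balanced", 27.6101, 7.2635, 8.8777),
    ("m16_balanced", 27.6091, 11.0158, 13.4638),
    ("p6_balanced", 27.6374, 0.2616, 0.3198),
    ("m4_balanced", 27.6079, 3.4408, 4.2054),
    ("m17", 2.7490, 4.4595, 4.5495),
    ("r10", 27.5836, 0.1991, 0.2433),
    ("n2", 27.6115, 2.7078, 3.3096),
    ("m1", 27.6087, 1.7991, 2.1989),
]

# (label, E kJ/mol, k at T_lo, k at T_hi); standard convention.
# m4 and r10 are omitted: their printed energies are mutually swapped.
TWO_TEMPERATURE_ROWS = [
    ("n6", 11.3399, 7.6784, 9.7517),
    ("m16", 12.3650, 11.5927, 15.0445),
    ("p6", 7.5775, 0.2812, 0.3299),
    ("m17", 10.2539, 4.2545, 5.2810),
    ("n2", 50.8636, 2.4062, 7.0300),
    ("m1", 1.2201, 1.9883, 2.0401),
]
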