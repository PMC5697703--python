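"""Benchmark reference values for the multiband design family.

``REFERENCE_AM_PHASES_DEG`` are best-known peak-minimizing antisymmetric
phase offsets for unit-spaced multiband modulation (degrees, slices ordered
outermost-to-outermost, central value = middle slice).  They are defined
only up to the problem's gauge freedoms (common time shift of the
modulation, global sign, slice-order flip); compare with
:func:`ampulse.phase_opt.gauge_match`.

``REFERENCE_SINGLE_BAND_TEFF`` are effective durations (hard-pulse-relative)
of the single-band linear-phase refocusing designs with 1% in/out-of-slice
spin-echo ripples, used as the regression anchor for the beta-filter design
rule.
"""

REFERENCE_AM_PHASES_DEG = {
    3: [73.6, 0, -73.6],
    4: [55.8, 78.6, -78.6, -55.8],
    5: [66.3, -56.9, 0, 56.9, -66.3],
    6: [96.9, 161.1, 66.3, -66.3, -161.1, -96.9],
    7: [147.9, -32.2, 5.9, 0, -5.9, 32.2, -147.9],
    8: [121.0, 12.6, 83.9, 114.1, -114.1, -83.9, -12.6, -121.0],
    9: [27.5, -152.8, -37.0, -24.0, 0, 24.0, 37.0, 152.8, -27.5],
    10: [96.4, -137.2, 166.9, 17.4, 42.2, -42.2, -17.4, -166.9, 137.2, -96.4],
    11: [80.5, 50.8, -106.2, 4.0, -85.6, 0, 85.6, -4.0, 106.2, -50.8, -80.5],
    12: [99.1, 25.4, 41.3, 125.5, -125.8, 56.4,
         -56.4, 125.8, -125.5, -41.3, -25.4, -99.1],
}

REFERENCE_SINGLE_BAND_TEFF = {
    2: 3.637,
    4: 8.270,
    6: 13.231,
    8: 18.156,
    10: 23.051,
}
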