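"""Canonical frequency-band layout shared by the EEG generator and feature code.

Eight sub-bands spanning 1-80 Hz. Band edges are integer spectral bins
(1 Hz resolution), closed on both sides; consecutive bands are contiguous so
the eight bands exactly partition the analysed 1-80 Hz range.
"""

from __future__ import annotations

BAND_NAMES: tuple[str, ...] = (
    "delta",
    "theta",
    "low_alpha",
    "high_alpha",
    "low_beta",
    "high_beta",
    "low_gamma",
    "high_gamma",
)

#: inclusive (lo, hi) bin edges in Hz at 1 Hz resolution.
#: The nominal delta band starts at 0.1 Hz, but a 1.5 s epoch cannot resolve
#: below ~1 Hz, so delta is computed over 1-4 Hz.
BAND_EDGES: dict[str, tuple[int, int]] = {
    "delta": (1, 4),
    "theta": (5, 7),
    "low_alpha": (8, 10),
    "high_alpha": (11, 13),
    "low_beta": (14, 21),
    "high_beta": (22, 30),
    "low_gamma": (31, 50),
    "high_gamma": (51, 80),
}

FMIN: float = 1.0
#: upper edge of the highest band
FMAX: float = 80.0
#: upper edge of the relative-power denominator: each bin is expressed as a
#: percentage of the total power of the whole spectrum (up to the Nyquist
#: frequency of the 1000 Hz recording), so the eight band shares partition
#: less than 100 % and the remainder sits in the broadband tail
FMAX_TOTAL: float = 500.0

#: default centre frequency (Hz) of the band-limited oscillator per band.
DEFAULT_OSC_FREQS: tuple[float, ...] = (2.5, 6.0, 9.0, 12.0, 17.5, 26.0, 40.0, 65.0)

N_BANDS = len(BAND_NAMES)
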