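"""Standard 1/3-octave band definitions and A-weighting.

Bands follow the base-10 nominal series (ANSI S1.6 / IEC 61260 preferred
frequencies).  A band with nominal centre ``fc`` has exact edges
``fc * 10**(-1/20)`` and ``fc * 10**(+1/20)``, so that three bands span one
decade-based octave.
"""

from __future__ import annotations

import numpy as np

# Nominal centre frequencies (Hz) of the base-10 one-third-octave series
# covering the analysis range used for terrestrial soundscape monitoring.
NOMINAL_THIRD_OCTAVE_CENTERS: tuple[float, ...] = (
    12.5, 16.0, 20.0, 25.0, 31.5, 40.0, 50.0, 63.0, 80.0, 100.0,
    125.0, 160.0, 200.0, 250.0, 315.0, 400.0, 500.0, 630.0, 800.0, 1000.0,
    1250.0, 1600.0, 2000.0, 2500.0, 3150.0, 4000.0, 5000.0, 6300.0,
    8000.0, 10000.0, 12500.0, 16000.0, 20000.0,
)

#: Default analysis series: 12.5 Hz – 6.3 kHz (28 bands).
DEFAULT_CENTERS: tuple[float, ...] = NOMINAL_THIRD_OCTAVE_CENTERS[:28]

_EDGE_RATIO = 10.0 ** (1.0 / 20.0)  # half-band ratio for base-10 thirds


def band_edges(centers) -> tuple[np.ndarray, np.ndarray]:
    """Lower and upper passband edges for nominal centres.

    Returns ``(low, high)`` arrays with ``low = fc / 10**(1/20)`` and
    ``high = fc * 10**(1/20)``.
    """
    c = np.asarray(centers, dtype=float)
    return c / _EDGE_RATIO, c * _EDGE_RATIO


def nominal_centers_between(fmin: float, fmax: float) -> np.ndarray:
    """Nominal centres with ``fmin <= fc <= fmax`` (inclusive on both ends)."""
    c = np.asarray(NOMINAL_THIRD_OCTAVE_CENTERS)
    return c[(c >= fmin) & (c <= fmax)]


def a_weighting_db(freq_hz) -> np.ndarray:
    """A-weighting gain in dB at the given frequencies (IEC 61672 analytic form).

    ``A(f) = 20 log10 R_A(f) + 2.00`` where ``R_A`` is the standard rational
    response; 0 dB at 1 kHz by construction of the +2.00 dB normalisation.
    """
    f = np.asarray(freq_hz, dtype=float)
    f2 = f**2
    ra = (12194.0**2 * f2**2) / (
        (f2 + 20.6**2)
        * np.sqrt((f2 + 107.7**2) * (f2 + 737.9**2))
        * (f2 + 12194.0**2)
    )
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(ra) + 2.00
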