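"""SuperDove (PSB.SD) band grid and band-index conventions.

All library code indexes bands 0-based; user-facing configuration and the
CLI use 1-based band numbers (band 2 = 492 nm blue, the bleaching
indicator band). Conversion happens only at the interface layer.
"""

from __future__ import annotations

import numpy as np

#: Center wavelengths (nm) of the 8 SuperDove bands, in band order.
SUPERDOVE_WAVELENGTHS_NM: tuple[int, ...] = (444, 492, 533, 566, 612, 666, 707, 866)

#: 0-based index of the blue band (492 nm) used for bleaching detection.
BLUE_IDX = 1

#: 0-based index of the NIR band (866 nm) used for glint correction and
#: land masking.
NIR_IDX = 7

#: 0-based indices averaged for the brightness (cloud) mask: bands 1-4.
BRIGHTNESS_IDX = (0, 1, 2, 3)

N_BANDS = len(SUPERDOVE_WAVELENGTHS_NM)


def wavelengths() -> np.ndarray:
    """Band-center wavelengths in nm as a float array."""
    return np.asarray(SUPERDOVE_WAVELENGTHS_NM, dtype=float)


def band_index(user_band: int) -> int:
    """Convert a 1-based user-facing band number to a 0-based index."""
    if not 1 <= user_band <= N_BANDS:
        raise ValueError(f"band must be in 1..{N_BANDS}, got {user_band}")
    return user_band - 1
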