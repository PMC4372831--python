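"""Bundled SYNTHETIC observed-web stand-in.

This module ships a constructed 9-plant x 4-bird quantitative web.  It is
**not field data**: the binary fill pattern (28 of 36 cells) and the positive
cell values were searched and numerically calibrated so that this package's
metric conventions reproduce a reference set of observed aggregate statistics
for a community of this shape:

* connectance 0.7777778 (28/36 by construction),
* interaction evenness 0.8341048 under the cells denominator (``ln 36``),
* interaction asymmetry 0.1602762 for plants and -0.2723253 for birds under
  species-then-guild averaging.

Its nestedness values (binary NODF, weighted nestedness) are NOT calibrated
to anything published; they are regression pins of this package's own
implementations on this particular matrix.  The stand-in supports
convention-pinning tests only and no ecological conclusion.
"""

from __future__ import annotations

import numpy as np

from .webs import QuantitativeWeb

#: Calibration targets the stand-in reproduces (package conventions).
SYNTHETIC_OBSERVED_TARGETS = {
    "connectance": 0.7777778,
    "interaction_evenness": 0.8341048,
    "asymmetry_plants": 0.1602762,
    "asymmetry_birds": -0.2723253,
}

_SYNTHETIC_MATRIX = np.array(
    [
        [20.137043, 27.437997, 28.185582, 0.963186],
        [22.375848, 29.581868, 0.0, 1.095588],
        [5.889746, 0.0, 30.420066, 1.134484],
        [22.259387, 0.0, 30.174236, 1.086353],
        [22.375617, 29.582471, 0.0, 1.092099],
        [0.0, 37.574488, 0.0, 1.186944],
        [0.0, 27.702878, 28.471884, 1.012302],
        [22.259437, 0.0, 30.174304, 1.085693],
        [20.15186, 27.438327, 28.186069, 0.964244],
    ]
)


def synthetic_observed_web() -> QuantitativeWeb:
    """The synthetic 9x4 stand-in web (see module docstring)."""
    return QuantitativeWeb(
        _SYNTHETIC_MATRIX.copy(),
        [f"plant_{i + 1}" for i in range(9)],
        [f"bird_{j + 1}" for j in range(4)],
    )
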