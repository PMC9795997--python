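"""Delta-notation <-> isotope-ratio conversions.

All model arithmetic is carried out in ratio space (R); per-mil values appear
only at the I/O boundary.  delta = R/R_std - 1, with VSMOW for 18O/16O and
VPDB for 13C/12C.
"""

from __future__ import annotations

import numpy as np

#: 18O/16O of Vienna Standard Mean Ocean Water
R_VSMOW = 2005.20e-6
#: 13C/12C of Vienna Peedee belemnite
R_VPDB = 11180.2e-6


def delta_to_ratio(delta_permil, r_std: float):
    """Convert a delta value (per mil) to an absolute isotope ratio."""
    return r_std * (1.0 + np.asarray(delta_permil, dtype=float) / 1000.0)


def ratio_to_delta(ratio, r_std: float):
    """Convert an absolute isotope ratio to a delta value (per mil)."""
    return (np.asarray(ratio, dtype=float) / r_std - 1.0) * 1000.0
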