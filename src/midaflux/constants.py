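"""Natural isotope abundances and element bookkeeping.

Abundances follow the IUPAC representative values.  Each element maps to an
array of fractional abundances indexed by nominal mass shift above the
lightest isotope (index 0 = monoisotopic).  Only H, C, N, O and S occur in
unmodified peptides and acyl lipids, which is all this package models.
"""

from __future__ import annotations

import numpy as np

#: natural 2H fraction of hydrogen (also the default unlabeled body-water value)
NATURAL_2H: float = 0.000115

#: per-element fractional abundance by mass shift (index = extra nominal mass)
NATURAL_ABUNDANCE: dict[str, np.ndarray] = {
    "H": np.array([0.999885, 0.000115]),
    "C": np.array([0.9893, 0.0107]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    # 32S, 33S, 34S, (no mass+3), 36S
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0, 0.0001]),
}

ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S")
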