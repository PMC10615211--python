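"""Small built-in reference tables.

:func:`bgc1_pulldown_table` carries the published filtered list of
starch-metabolic proteins enriched in the BGC1 affinity pulldown from
developing durum wheat endosperm (18 dpa): accession, protein name,
pulldown/control abundance ratio and its p-value, as printed.  Ratios
saturate at 100 and p-values floor at 1e-17 in the source export.
"""

from __future__ import annotations

import pandas as pd

from .io import ProteinQuantTable

__all__ = ["bgc1_pulldown_table"]

_BGC1_PULLDOWN_ROWS = [
    ("TRITD3Av1G038460.3", "MFP1.2", 100.0, 1e-17),
    ("TRITD1Av1G054690.1", "MFP1.1", 100.0, 1e-17),
    ("TRITD3Bv1G047250.3", "MFP1.2", 93.506, 1e-17),
    ("TRITD1Bv1G062760.3", "MFP1.1", 56.176, 1e-17),
    ("TRITD7Bv1G229280.2", "SBE1.3", 45.482, 1e-17),
    ("TRITD6Bv1G086030.1", "Brittle1 transporter 1", 26.309, 1e-17),
    ("TRITD7Av1G275430.16", "SBE1.1", 11.778, 1e-17),
    ("TRITD2Bv1G044170.1", "Disproportionating enzyme 2", 3.363, 0.0064),
    ("TRITD7Bv1G229250.2", "SBE1.1", 2.949, 0.0033),
    ("TRITD5Bv1G140970.6", "Phosphoglucose isomerase", 2.563, 0.0291),
    ("TRITD5Bv1G201740.3", "Plastidial alpha-glucan phosphorylase", 2.538, 0.0211),
    ("TRITD2Av1G048150.2", "Disproportionating enzyme 1", 2.359, 0.0428),
    ("TRITD7Bv1G038900.1", "SS2a", 2.308, 0.0006),
]


def bgc1_pulldown_table() -> ProteinQuantTable:
    """The published BGC1 pulldown enrichment list (13 proteins)."""
    frame = pd.DataFrame(
        _BGC1_PULLDOWN_ROWS, columns=["accession", "protein", "ratio", "p_value"]
    )
    return ProteinQuantTable(frame)
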