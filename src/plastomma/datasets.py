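"""Published overview metrics for the ten-plastome Pleurothallidinae set.

These are the printed per-taxon genome metrics (GenBank accessions
MH979332, KJ566305, and the eight companion depositions): total length,
LSC/SSC/IR lengths in bp, and %GC.  They are inputs for the desk-scale
correlation analyses; note the *Anathallis obovata* row violates
additivity (total != LSC + SSC + 2 IR by 3,000 bp — its printed LSC is
inconsistent with the stated LSC range, whose minimum implies LSC =
83,694).  The toolkit flags this rather than silently fixing it; see
:func:`plastomma.metrics.correlation_suite` for the explicit fix mode.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # taxon, total_bp, lsc_bp, ssc_bp, ir_bp, gc_percent
    ("Acianthera recurva", 148246, 84871, 10573, 26401, 37.0),
    ("Anathallis microphyta", 154558, 84597, 15993, 26984, 37.0),
    ("Anathallis obovata", 155515, 86694, 17923, 26949, 37.1),
    ("Dryadella lilliputiana", 156807, 84943, 17992, 26936, 37.1),
    ("Masdevallia picturata", 156045, 84948, 18029, 26534, 36.9),
    ("Myoxanthus exasperatus", 157905, 85605, 18260, 27020, 37.1),
    ("Octomeria grandiflora", 155284, 84916, 17874, 26247, 36.9),
    ("Pabstiella mirabilis", 150317, 83699, 16134, 25242, 37.1),
    ("Stelis grandiflora", 157535, 85205, 18444, 26943, 36.9),
    ("Stelis montserratii", 157479, 85147, 18366, 26983, 36.9),
]


def pleurothallidinae_metrics() -> pd.DataFrame:
    """The published ten-taxon genome-metrics table (one row per taxon)."""
    return pd.DataFrame(
        _ROWS,
        columns=["taxon", "total_bp", "lsc_bp", "ssc_bp", "ir_bp", "gc_percent"],
    )
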