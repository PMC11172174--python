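"""Small published reference datasets bundled with the package.

These are printed summary tables, not sequencing data; they let the
classification layers run on real numbers without any download.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["derepressed_te_antisense_rpm", "DEREPRESSED_TE_CLASSES"]

#: TE class of each of the seven TE families derepressed in
#: D. melanogaster x D. simulans hybrid ovaries.
DEREPRESSED_TE_CLASSES = {
    "blood": "LTR",
    "Burdock": "LTR",
    "gypsy12": "LTR",
    "diver": "LTR",
    "HMS-Beagle": "LTR",
    "rover": "LTR",
    "jockey": "LINE",
}

_ANTISENSE_RPM = {
    # family: (sim, mel, hybrid) antisense TE-mapped piRNAs, rpm (0-3 mm)
    "blood": (5602.2, 2904.2, 1112.3),
    "Burdock": (627.6, 1072.6, 80.3),
    "gypsy12": (1574.0, 1011.6, 131.7),
    "diver": (1163.3, 424.4, 52.6),
    "HMS-Beagle": (1834.4, 407.8, 89.5),
    "rover": (51.0, 1335.5, 362.7),
    "jockey": (182.3, 375.3, 45.6),
}


def derepressed_te_antisense_rpm() -> pd.DataFrame:
    """Antisense TE-mapped piRNA abundance (rpm, 0-3 mismatches) in
    D. simulans, D. melanogaster and hybrid ovaries for the seven TE
    families overexpressed in hybrid ovaries.

    Columns: ``sim``, ``mel``, ``hybrid``; index: family name.
    """
    return pd.DataFrame.from_dict(
        _ANTISENSE_RPM, orient="index", columns=["sim", "mel", "hybrid"]
    ).rename_axis("family")
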