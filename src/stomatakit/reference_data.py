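"""Published cultivar-level stomatal trait means for the maize hybrid
Jingnongke 728 and its parental inbred lines Jing 2416 (paternal) and
MC01 (maternal).

These are pooled means over reproductive stages and leaf layers from a
published abaxial-epidermis phenotyping study of these three cultivars,
kept here so the worked examples and consistency checks (roundness
arithmetic, heterosis sign pattern) run without any image data.  Units:
SD mm^-2; SW, SL, SP um; SA, GCPA, SCA um^2; SR, SE, PGCPA, PSCA
dimensionless.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["CULTIVAR_TRAIT_MEANS", "cultivar_means_frame", "HYBRID", "PARENTS"]

HYBRID = "728"
PARENTS = ("2416", "MC01")

#: Pooled trait means by cultivar (rows) and trait (columns).
CULTIVAR_TRAIT_MEANS: dict[str, dict[str, float]] = {
    "2416": {
        "SW": 55.45, "SL": 90.68, "SA": 3809.86, "SP": 281.48, "SR": 0.61, "SE": 0.77,
        "SCA": 1891.25, "PSCA": 0.49, "GCPA": 1919.61, "PGCPA": 0.50, "SD": 87.21,
    },
    "MC01": {
        "SW": 56.66, "SL": 94.09, "SA": 4053.70, "SP": 281.63, "SR": 0.65, "SE": 0.78,
        "SCA": 2102.48, "PSCA": 0.52, "GCPA": 1951.22, "PGCPA": 0.48, "SD": 78.64,
    },
    "728": {
        "SW": 55.86, "SL": 97.20, "SA": 4140.05, "SP": 288.45, "SR": 0.63, "SE": 0.80,
        "SCA": 2122.02, "PSCA": 0.51, "GCPA": 2018.03, "PGCPA": 0.49, "SD": 74.95,
    },
}


def cultivar_means_frame() -> pd.DataFrame:
    """The cultivar trait means as a DataFrame indexed by cultivar."""
    return pd.DataFrame(CULTIVAR_TRAIT_MEANS).T
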