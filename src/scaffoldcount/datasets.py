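"""Bundled example data: per-field densities from a two-scaffold experiment.

Ten fields of view were analyzed in each of two fibrin-collagen hydrogel
scaffolds seeded with human dermal fibroblasts at a two-fold difference in
concentration (variant 1: 90 cells/mm^3, variant 2: 180 cells/mm^3) and
cultured for three days before counting. Values are cells per mm^3.
"""

from __future__ import annotations

import pandas as pd

SEEDING_DENSITY = {"var1": 90.0, "var2": 180.0}

VAR1_DENSITIES = (
    301.73, 250.05, 203.95, 238.87, 308.02,
    276.59, 321.99, 213.03, 273.10, 299.64,
)

VAR2_DENSITIES = (
    645.38, 648.17, 648.87, 637.00, 609.06,
    553.88, 602.07, 681.70, 662.84, 743.86,
)


def load_two_scaffold_validation() -> pd.DataFrame:
    """Per-field densities of the two-scaffold experiment, long format.

    Columns: ``variant`` ("var1"/"var2"), ``field`` (1-10),
    ``cells_per_mm3``.
    """
    rows = [
        {"variant": var, "field": i, "cells_per_mm3": k}
        for var, values in (("var1", VAR1_DENSITIES), ("var2", VAR2_DENSITIES))
        for i, k in enumerate(values, start=1)
    ]
    return pd.DataFrame(rows)
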