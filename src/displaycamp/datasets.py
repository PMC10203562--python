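"""Built-in reference data of the bococizumab optimization campaign.

The characterization panel holds the published biophysical assay results
for parental bococizumab, ten mammalian-display-selected variants and
trastuzumab (a well-behaved control): AC-SINS score (nm), polyreactivity
ELISA score (blank-subtracted OD450), DLS polydispersity index, analytical
HIC retention time (min), nanoDSF Tm (deg C) and SPR KD (pM).  Variants
are named after their VH 53/54 + VL 94/95 residues (parental = PFLW).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["characterization_panel", "top_variant_enrichment"]

_PANEL_ROWS = [
    # variant, category, acsins_nm, polyreactivity, pdi, hic_rt_min, tm_c, kd_pm
    ("PFLW", "parental", 22.6, 1.56, 0.30, 4.6, 65.9, 250.0),
    ("SEGQ", "best", 1.1, 0.77, 0.04, 3.9, 67.0, 350.0),
    ("AEGQ", "best", 0.7, 0.44, 0.05, 3.7, 67.7, 190.0),
    ("AEPA", "best", 0.8, 0.43, 0.05, 3.7, 67.4, 210.0),
    ("PEGQ", "best", 1.4, 0.53, 0.19, 3.7, 68.5, 200.0),
    ("PENW", "affinity", 1.2, 0.49, 0.07, 3.7, 67.2, 240.0),
    ("PERQ", "affinity", 3.5, 0.86, 0.38, 3.6, 68.9, 250.0),
    ("EDGM", "display", 0.2, 0.15, 0.14, 3.8, 67.5, 660.0),
    ("PFGQ", "vl_only", 19.2, 1.54, 0.59, 4.3, 67.6, 250.0),
    ("SELW", "vh_only", 2.5, 0.87, 0.05, 4.1, 65.8, 270.0),
    ("PELW", "point_mutant", 1.4, 0.72, 0.46, 3.9, 66.6, 190.0),
    ("trastuzumab", "control", 0.5, 0.15, 0.03, 4.4, 70.6, float("nan")),
]


def characterization_panel() -> pd.DataFrame:
    """Measured assay panel of the campaign, indexed by variant name."""
    frame = pd.DataFrame(
        _PANEL_ROWS,
        columns=[
            "variant",
            "category",
            "acsins_nm",
            "polyreactivity",
            "pdi",
            "hic_rt_min",
            "tm_c",
            "kd_pm",
        ],
    )
    return frame.set_index("variant")


_TOP_VARIANTS = [
    # population, vh_pair, vl_pair, normalized_count_pct, enrichment_factor
    ("best", "SE", "GQ", 18.46, 11700.0),
    ("best", "AE", "GQ", 2.53, 6800.0),
    ("best", "AE", "PA", 4.28, 4200.0),
    ("best", "PE", "GQ", 2.64, 2600.0),
    ("best", "PE", "VM", 2.32, 2300.0),
    ("best", "PE", "TS", 1.47, 2300.0),
    ("best", "RS", "CG", 10.40, 2200.0),
    ("best", "PE", "VS", 5.13, 1500.0),
    ("best", "PF", "LW", 0.08, 0.06),
    ("affinity", "PE", "RQ", 4.33, 2700.0),
    ("affinity", "PE", "NW", 1.75, 2400.0),
    ("affinity", "PE", "VM", 0.68, 700.0),
    ("affinity", "PE", "GC", 0.88, 500.0),
    ("affinity", "PE", "SV", 1.07, 300.0),
    ("display", "ED", "GM", 1.97, 2100.0),
    ("display", "DD", "HS", 0.63, 1300.0),
    ("display", "DD", "MG", 0.40, 500.0),
    ("display", "EQ", "AT", 0.44, 200.0),
    ("display", "ED", "GE", 0.37, 200.0),
]


def top_variant_enrichment() -> pd.DataFrame:
    """Published top-variant normalized counts (%) and enrichment factors
    per sorted population (parental = PF/LW, final-round EF 0.06)."""
    return pd.DataFrame(
        _TOP_VARIANTS,
        columns=[
            "population",
            "vh_pair",
            "vl_pair",
            "normalized_count_pct",
            "enrichment_factor",
        ],
    )
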