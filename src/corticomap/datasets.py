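"""Small reference datasets shipped with the package."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["macaque_area_table", "macaque_method_pairs"]

# Published per-hemisphere surface areas (mm²) of the densely myelinated
# V5/MT + MST complex in seven rhesus macaques, measured in vivo from
# T1w/T2w myelin-weighted maps (top-third intensity rule) and postmortem
# from Gallyas-stained section series.  Dashes in the source table are
# missing measurements and stay missing here.
_TABLE = {
    "mri_lh": [71.4, np.nan, 94.7, 88.5, np.nan, 94.1, 69.2],
    "hist_lh": [66.0, 71.7, 90.3, 81.6, 68.8, 89.3, np.nan],
    "mri_rh": [79.1, np.nan, 86.2, 83.6, np.nan, 82.3, 74.6],
    "hist_rh": [np.nan, np.nan, np.nan, np.nan, 65.1, np.nan, np.nan],
}
_SUBJECTS = ["M126", "M127", "M128", "M129", "M130", "M131", "M132"]


def macaque_area_table() -> pd.DataFrame:
    """Macaque V5/MT+MST area measurements (mm²) by method and hemisphere.

    Columns: ``mri_lh``, ``hist_lh``, ``mri_rh``, ``hist_rh``; one row per
    animal.  NaN marks hemispheres without a measurement.
    """
    return pd.DataFrame(_TABLE, index=_SUBJECTS)


def macaque_method_pairs() -> list[tuple[float, float]]:
    """Complete (sMRI area, histology area) pairs for method agreement.

    Only hemispheres with both an in vivo and a histological measurement
    qualify; in this table those are four left hemispheres.
    """
    df = macaque_area_table()
    pairs = []
    for _, row in df.iterrows():
        for mri_col, hist_col in (("mri_lh", "hist_lh"), ("mri_rh", "hist_rh")):
            if np.isfinite(row[mri_col]) and np.isfinite(row[hist_col]):
                pairs.append((float(row[mri_col]), float(row[hist_col])))
    return pairs
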