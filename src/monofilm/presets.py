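"""Named presets spanning the observed ranges of the studied systems.

The isotherm presets parameterise the generator from published mean values of
A_lim, pi_coll, pi_plateau and Cs^-1_max for phosphatidylcholine monolayers
(di-18:3 and di-16:0 films and their 1:1 mixture, pure and with castasterone
(CS) / homocastasterone (HCS) at a 4:1 lipid:steroid ratio) at 10, 20 and
30 C.  They emulate the curve *families* — liquid-expanded tail, optional
LE/LC plateau, affine condensed branch, collapse — not the experimental
curves themselves.

LE-type systems whose maximal modulus is below their collapse pressure
(di-18:3 at 10 C) cannot be represented by an affine condensed branch and
have no generator preset; their temperature-normalisation analysis uses the
printed parameter values directly (:func:`pc183_feature_table`).
"""

from __future__ import annotations

import pandas as pd

from .reporting import feature_table

__all__ = [
    "ISOTHERM_PRESETS",
    "ZETA_PRESETS",
    "S_PROFILE_PRESET",
    "PC183_TABLE",
    "pc183_feature_table",
]

# name -> (A_lim [A^2], pi_coll [mN/m], pi_plateau [mN/m] | None,
#          Cs^-1_max [mN/m], temperature [C])
ISOTHERM_PRESETS: dict[str, tuple[float, float, float | None, float, float]] = {
    "pc183_20C": (74.3, 42.4, None, 93.8, 20.0),
    "pc183_30C": (77.3, 39.9, None, 77.6, 30.0),
    "pc183_hcs_20C": (80.0, 40.6, None, 64.7, 20.0),
    "pc183_pc160_20C": (63.4, 43.4, None, 98.6, 20.0),
    "pc160_10C": (40.8, 69.8, None, 221.5, 10.0),
    "pc160_20C": (40.1, 62.3, 14.1, 187.8, 20.0),
    "pc160_30C": (41.1, 47.1, 34.2, 110.7, 30.0),
    "pc160_cs_20C": (41.3, 55.0, 23.7, 152.6, 20.0),
    "pc160_cs075_10C": (41.0, 65.1, 23.2, 215.4, 10.0),
}

# Zeta potentials [mV] of liposome suspensions: sample -> (mean, SE).
# "bowmanT_*" are liposomes from barley phospholipids (plants grown at T C);
# "synthetic_*" is the PC 18:3 + PG 1:1 mimic; "*_water" are the bare
# steroids dispersed in water.
ZETA_PRESETS: dict[str, tuple[float, float]] = {
    "bowman20_native": (-81.6, 1.7),
    "bowman20_hcs": (-52.3, 2.3),
    "bowman20_cs": (-77.5, 2.5),
    "bowman20_hcs_cs": (-68.5, 2.7),
    "bowman5_native": (-101.0, 3.0),
    "bowman5_hcs": (-68.3, 2.0),
    "bowman5_cs": (-74.1, 2.2),
    "bowman5_hcs_cs": (-71.2, 2.1),
    "bowman27_native": (-86.4, 2.6),
    "bowman27_hcs": (-57.2, 1.7),
    "bowman27_cs": (-59.5, 1.8),
    "bowman27_hcs_cs": (-58.3, 1.7),
    "synthetic_native": (-90.0, 2.7),
    "synthetic_hcs": (-64.5, 1.9),
    "synthetic_cs": (-89.1, 2.8),
    "synthetic_hcs_cs": (-79.2, 2.4),
    "cs_water": (-14.6, 0.4),
    "cs_hcs_water": (-5.76, 0.2),
    "hcs_water": (-3.11, 0.1),
}

# Qualitative temperature profile of the 16-SASL order parameter in the
# PC 18:3 + PG 16:0 liposome: S declines from 5 to 20 C and rises again at
# 30 C.  Magnitudes are generator defaults, not measured values.
S_PROFILE_PRESET: dict[float, float] = {
    5.0: 0.20,
    10.0: 0.17,
    15.0: 0.15,
    20.0: 0.13,
    30.0: 0.16,
}

# Printed monolayer parameters of the pure di-18:3 phosphatidylcholine film
# (mean, SE) per temperature, used for the percent-of-20-C analysis.
PC183_TABLE: dict[float, dict[str, tuple[float, float]]] = {
    10.0: {"A_lim": (62.9, 0.1), "pi_coll": (28.2, 0.3), "cs_inv_max": (24.2, 0.5)},
    20.0: {"A_lim": (74.3, 0.3), "pi_coll": (42.4, 0.3), "cs_inv_max": (93.8, 0.4)},
    30.0: {"A_lim": (77.3, 0.5), "pi_coll": (39.9, 0.4), "cs_inv_max": (77.6, 0.4)},
}


def pc183_feature_table(n: int = 3) -> pd.DataFrame:
    """Long-format feature table of the pure di-18:3 PC film at 10/20/30 C."""
    rows = []
    for temperature, params in PC183_TABLE.items():
        for parameter, (value, se) in params.items():
            rows.append(("PC 18:3", temperature, parameter, value, se, n))
    return feature_table(rows)
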